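"""Genotype matrix container, VCF input/output, site filters and LD pruning.

Genotypes are stored as alt-allele dosages (0/1/2) in a compact integer
matrix, ``MISSING = -1``. Site filters reproduce a standard GBS cleaning
chain: diallelic-only, call rate >= 95%, mean depth >= 5, pooled minor allele
frequency >= 0.10, followed by sliding-window LD pruning with a variance
inflation factor (VIF) threshold.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

LOCUS_COLUMNS = ["contig", "pos", "ref", "alt", "diallelic"]


class VcfParseError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Individuals x loci alt-allele dosage matrix with sample metadata.

    ``genotypes[i, l]`` is the number of alt alleles (0, 1, 2) of individual
    ``i`` at locus ``l``, or ``MISSING``. ``loci`` is a DataFrame with columns
    ``contig, pos, ref, alt, diallelic``; ``depth`` (optional) holds the
    per-genotype read depth.
    """

    genotypes: np.ndarray
    individual_ids: list[str]
    population_ids: list[str]
    loci: pd.DataFrame
    depth: np.ndarray | None = None
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        n, m = self.genotypes.shape
        if len(self.individual_ids) != n or len(self.population_ids) != n:
            raise ValueError("individual/population id count mismatch")
        if len(self.loci) != m:
            raise ValueError("locus metadata count mismatch")
        dup = self.loci.duplicated(subset=["contig", "pos"])
        if dup.any():
            raise ValueError("duplicate loci by (contig, position)")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def missing_fraction(self) -> float:
        return float(np.mean(self.genotypes == MISSING))

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.population_ids:
            seen.setdefault(p)
        return list(seen)

    def locus_ids(self) -> list[str]:
        return [f"{c}:{p}" for c, p in zip(self.loci["contig"], self.loci["pos"])]

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return replace(
            self,
            genotypes=self.genotypes[:, keep],
            loci=self.loci.iloc[keep].reset_index(drop=True),
            depth=None if self.depth is None else self.depth[:, keep],
            truth=None if self.truth is None else self.truth.iloc[keep].reset_index(drop=True),
        )

    def subset_individuals(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return replace(
            self,
            genotypes=self.genotypes[keep],
            individual_ids=[self.individual_ids[i] for i in keep],
            population_ids=[self.population_ids[i] for i in keep],
            depth=None if self.depth is None else self.depth[keep],
        )


@dataclass
class FilterReport:
    """Loci removed per rule, in the order the rules were applied."""

    n_input: int
    removed: dict[str, int] = field(default_factory=dict)

    @property
    def n_output(self) -> int:
        return self.n_input - sum(self.removed.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rule": list(self.removed), "removed": list(self.removed.values())}
        )


# ---------------------------------------------------------------------------
# VCF I/O


def read_vcf(path: str | Path, pop_map: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records are retained but flagged ``diallelic = False`` so
    the filter stage can drop them. Per-genotype DP is captured when the
    FORMAT declares it. Population ids come from ``pop_map`` (sample ->
    population) or, failing that, from the sample-name prefix before the
    last underscore.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    gts, rows, depths = [], [], []
    has_depth = False
    for i, rec in enumerate(vcf):
        try:
            n_alt = len(rec.ALT)
            # genotype dosage of the first alt allele; anything but {0,1}
            # alleles counts as non-diallelic content
            g = np.asarray(rec.genotype.array())[:, :2]
            dosage = np.where((g < 0).any(axis=1), MISSING, (g == 1).sum(axis=1))
            gts.append(dosage.astype(np.int16))
            rows.append(
                (rec.CHROM, rec.POS, rec.REF, ",".join(rec.ALT), n_alt == 1)
            )
            try:
                d = rec.format("DP")
            except KeyError:
                d = None
            if d is not None:
                has_depth = True
                depths.append(np.where(d[:, 0] < 0, 0, d[:, 0]))
            else:
                depths.append(np.full(len(samples), -1))
        except Exception as exc:
            raise VcfParseError(f"malformed VCF record #{i + 1} in {path}: {exc}") from exc

    if not gts:
        raise VcfParseError(f"no variant records in {path}")
    geno = np.stack(gts, axis=1)
    loci = pd.DataFrame(rows, columns=LOCUS_COLUMNS)
    if pop_map is not None:
        pops = [pop_map[s] for s in samples]
    else:
        pops = [s.rsplit("_", 1)[0] for s in samples]
    depth = np.stack(depths, axis=1).astype(float) if has_depth else None
    if depth is not None:
        depth[depth < 0] = np.nan
    return GenotypeMatrix(geno, samples, pops, loci, depth=depth)


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a diallelic dosage matrix as a minimal VCFv4.2 with GT (and DP)."""
    path = Path(path)
    fmt = "GT:DP" if matrix.depth is not None else "GT"
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if matrix.depth is not None:
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    for contig in matrix.loci["contig"].unique():
        lines.append(f"##contig=<ID={contig}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.individual_ids)
    )
    for l in range(matrix.n_loci):
        row = matrix.loci.iloc[l]
        cells = []
        for i in range(matrix.n_individuals):
            gt = gt_code[int(matrix.genotypes[i, l])]
            if matrix.depth is not None:
                d = matrix.depth[i, l]
                cells.append(f"{gt}:{'.' if np.isnan(d) else int(d)}")
            else:
                cells.append(gt)
        lines.append(
            f"{row.contig}\t{row.pos}\t{row.contig}:{row.pos}\t{row.ref}\t{row.alt}"
            f"\t.\tPASS\t.\t{fmt}\t" + "\t".join(cells)
        )
    try:
        Path(path).write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing VCF {path}: {exc}") from exc


def write_dosage_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        matrix.genotypes, index=matrix.individual_ids, columns=matrix.locus_ids()
    )
    df.insert(0, "population", matrix.population_ids)
    df.to_csv(path, sep="\t", index_label="individual")


# ---------------------------------------------------------------------------
# Site filters


def apply_site_filters(
    matrix: GenotypeMatrix,
    min_call_rate: float = 0.95,
    min_mean_depth: float = 5.0,
    min_maf: float = 0.10,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the site filters in fixed order.

    Order: diallelic -> call rate -> mean depth (skipped when no DP is
    stored) -> MAF. MAF is the pooled minor-allele frequency over called
    genotypes of all individuals; the threshold is inclusive (MAF exactly at
    the threshold is retained) and evaluated in exact integer arithmetic.
    """
    report = FilterReport(matrix.n_loci)
    cur = matrix

    keep = cur.loci["diallelic"].to_numpy(dtype=bool)
    report.removed["non_diallelic"] = int((~keep).sum())
    cur = cur.subset_loci(keep)

    called = cur.genotypes != MISSING
    keep = called.mean(axis=0) >= min_call_rate
    report.removed["call_rate"] = int((~keep).sum())
    cur = cur.subset_loci(keep)

    if cur.depth is not None:
        mean_dp = np.nanmean(np.where(cur.genotypes != MISSING, cur.depth, np.nan), axis=0)
        keep = mean_dp >= min_mean_depth
        report.removed["mean_depth"] = int((~keep).sum())
        cur = cur.subset_loci(keep)
    else:
        report.removed["mean_depth"] = 0

    called = cur.genotypes != MISSING
    alt = np.where(called, cur.genotypes, 0).sum(axis=0).astype(np.int64)
    tot = 2 * called.sum(axis=0).astype(np.int64)
    minor = np.minimum(alt, tot - alt)
    # minor/tot >= min_maf, exactly, avoiding float boundary artefacts
    keep = (tot > 0) & (minor * 10**6 >= np.round(min_maf * 10**6).astype(np.int64) * tot)
    report.removed["maf"] = int((~keep).sum())
    cur = cur.subset_loci(keep)

    if cur.n_loci == 0:
        raise ValueError("all loci removed by site filters")
    return cur, report


# ---------------------------------------------------------------------------
# LD pruning (VIF)


def _window_vifs(X: np.ndarray) -> np.ndarray:
    """VIF of each column of X against the others (columns mean-imputed,
    centered). Perfect collinearity yields inf."""
    k = X.shape[1]
    vifs = np.empty(k)
    Xc = X - X.mean(axis=0)
    for j in range(k):
        others = np.delete(Xc, j, axis=1)
        y = Xc[:, j]
        ss_tot = float(y @ y)
        if ss_tot <= 1e-12:
            vifs[j] = 1.0  # constant column carries no LD information
            continue
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        r2 = 1.0 - float(resid @ resid) / ss_tot
        r2 = min(max(r2, 0.0), 1.0)
        vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def ld_prune_vif(
    matrix: GenotypeMatrix,
    window: int = 5,
    step: int = 5,
    vif_threshold: float = 2.0,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Sliding-window VIF pruning (plink ``--indep`` style).

    Windows of ``window`` consecutive loci advance by ``step``. Within a
    window, missing dosages are mean-imputed, and while any locus has
    VIF > threshold the locus with the largest VIF is removed; among exact
    ties the later locus by position is removed (the first is kept).
    """
    G = matrix.genotypes.astype(float)
    G[matrix.genotypes == MISSING] = np.nan
    col_mean = np.nanmean(G, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(G))
    G[inds] = col_mean[inds[1]]

    m = matrix.n_loci
    keep_mask = np.ones(m, dtype=bool)
    start = 0
    while start < m:
        idx = [j for j in range(start, min(start + window, m)) if keep_mask[j]]
        while len(idx) >= 2:
            vifs = _window_vifs(G[:, idx])
            worst = vifs.max()
            if not (worst > vif_threshold):
                break
            # remove the LAST position among maximal VIFs (keep first)
            drop_local = int(np.flatnonzero(vifs == worst)[-1])
            keep_mask[idx[drop_local]] = False
            idx.pop(drop_local)
        start += step

    report = FilterReport(m, {"vif": int((~keep_mask).sum())})
    return matrix.subset_loci(keep_mask), report
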