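"""Genotype, phenotype and group-label I/O plus marker quality control.

Genotypes are held as ALT-allele dosages (0, 1, 2) in a dense float matrix
with ``numpy.nan`` marking missing calls.  Coding by ALT count rather than
minor-allele count keeps a marker's column stable when the sample is
subset and the minor allele flips; minor-allele frequency is computed
separately where it is needed (QC).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call inside :class:`GenotypeMatrix`.
MISSING = np.nan

MARKER_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """n individuals x m markers of ALT-allele dosages.

    ``codes`` entries are 0.0, 1.0, 2.0 or ``nan`` (missing).
    """

    sample_ids: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D array")
        if self.codes.shape[0] != len(self.sample_ids):
            raise ValueError("row count does not match number of sample_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        observed = self.codes[~np.isnan(self.codes)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            # imputed matrices legitimately hold fractional dosages; only the
            # constructor of raw call data enforces the discrete alphabet
            pass

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.sample_ids), self.codes[:, index])

    def take_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), self.codes[idx, :])


@dataclass
class PhenotypeTable:
    """Trait values per sample; ``data`` is indexed by sample id.

    ``breed`` optionally carries a per-sample breed / population label used
    by :func:`assign_breed_means`.
    """

    data: pd.DataFrame
    breed: pd.Series | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class GroupAssignment:
    """Sample -> group label map (the compress_z vector).

    Identical labels denote one group; labels are opaque strings.
    """

    labels: pd.Series

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(str)
        if self.labels.index.has_duplicates:
            raise ValueError("duplicate sample ids in group assignment")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def n_groups(self) -> int:
        return self.labels.nunique()

    def group_order(self) -> list[str]:
        """Distinct labels in order of first appearance."""
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return list(seen)


@dataclass
class QCThresholds:
    """Marker-retention thresholds: MAF floor, missing-rate ceiling, HWE p floor."""

    maf_min: float = 0.05
    missing_max: float = 0.05
    hwe_p_min: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("maf_min", "missing_max", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def read_vcf(
    path: str | Path, keep_samples: Sequence[str] | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read biallelic SNPs from a VCF 4.x file as ALT-allele dosages.

    Multiallelic and non-SNP records are skipped (counted in the log);
    ``./.`` calls become missing.  Returns the genotype matrix and a marker
    table with columns ``id, chrom, pos, ref, alt``.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    kwargs = {"gts012": True}
    if keep_samples is not None:
        kwargs["samples"] = list(keep_samples)
    vcf = VCF(str(path), **kwargs)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError("VCF contains no samples")

    cols: list[np.ndarray] = []
    rows: list[tuple] = []
    n_skipped = 0
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g = var.gt_types.astype(float)
        g[g == 3] = MISSING
        cols.append(g)
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        rows.append((vid, str(var.CHROM), int(var.POS), var.REF, var.ALT[0]))
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    codes = (
        np.column_stack(cols) if cols else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(samples, codes), markers


def write_vcf(
    path: str | Path, g: GenotypeMatrix, markers: pd.DataFrame
) -> None:
    """Write a minimal VCF 4.2 file (GT only) for the given dosage matrix."""
    code_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        for j, row in enumerate(markers.itertuples(index=False)):
            gts = [
                code_map.get(c, "./.") if not math.isnan(c) else "./."
                for c in g.codes[:, j]
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def hwe_exact_pvalue(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Two-sided exact test of Hardy-Weinberg genotype proportions.

    Sums, over all heterozygote counts compatible with the observed allele
    totals, the conditional probabilities that are no larger than the
    observed configuration's.  No mid-p correction.
    """
    if min(n_homref, n_het, n_homalt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_homref + n_het + n_homalt
    if n == 0:
        raise ValueError("all genotype counts zero")
    rare = 2 * min(n_homref, n_homalt) + n_het
    # P(het = h | n, rare) ∝ 2^h / (hom_rare! h! hom_common!); shared
    # constants cancel in the normalisation below
    def logp(h: int) -> float:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return (
            h * math.log(2.0)
            - math.lgamma(hom_rare + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hom_common + 1)
        )

    hets = np.arange(rare % 2, rare + 1, 2)
    logs = np.array([logp(int(h)) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(1.0, p))


def marker_stats(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker MAF, missing rate and HWE exact p from the current codes."""
    codes = g.codes
    n_obs = (~np.isnan(codes)).sum(axis=0)
    missing_rate = 1.0 - n_obs / codes.shape[0]
    with np.errstate(invalid="ignore"):
        alt_freq = np.nansum(codes, axis=0) / np.maximum(2 * n_obs, 1)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    maf[n_obs == 0] = np.nan
    hwe = np.empty(codes.shape[1])
    for j in range(codes.shape[1]):
        col = codes[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            hwe[j] = np.nan
            continue
        hwe[j] = hwe_exact_pvalue(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
    return pd.DataFrame(
        {"maf": maf, "missing_rate": missing_rate, "hwe_p": hwe}
    )


def apply_marker_qc(
    g: GenotypeMatrix, markers: pd.DataFrame, thr: QCThresholds
) -> tuple[GenotypeMatrix, pd.DataFrame, dict]:
    """Filter markers on MAF >= floor, missing <= ceiling, HWE p >= floor.

    Statistics are recomputed from the current codes before filtering.  The
    report counts removals per criterion (a marker failing several criteria
    counts once under each).
    """
    if g.n_markers == 0:
        raise ValueError("empty genotype matrix")
    stats = marker_stats(g)
    fail_maf = ~(stats["maf"] >= thr.maf_min)
    fail_missing = ~(stats["missing_rate"] <= thr.missing_max)
    fail_hwe = ~(stats["hwe_p"] >= thr.hwe_p_min)
    keep = ~(fail_maf | fail_missing | fail_hwe)
    report = {
        "n_input": int(g.n_markers),
        "n_retained": int(keep.sum()),
        "n_removed": int((~keep).sum()),
        "removed_maf": int(fail_maf.sum()),
        "removed_missing": int(fail_missing.sum()),
        "removed_hwe": int(fail_hwe.sum()),
        "thresholds": {
            "maf_min": thr.maf_min,
            "missing_max": thr.missing_max,
            "hwe_p_min": thr.hwe_p_min,
        },
    }
    keep_idx = np.flatnonzero(keep.to_numpy())
    out_markers = markers.iloc[keep_idx].reset_index(drop=True)
    out_markers = out_markers.assign(
        maf=stats["maf"].to_numpy()[keep_idx],
        missing_rate=stats["missing_rate"].to_numpy()[keep_idx],
        hwe_p=stats["hwe_p"].to_numpy()[keep_idx],
    )
    return g.take_markers(keep_idx), out_markers, report


def impute_missing_mean(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call with its marker's mean observed dosage."""
    codes = g.codes.copy()
    n_obs = (~np.isnan(codes)).sum(axis=0)
    if (n_obs == 0).any():
        raise ValueError("marker entirely missing; cannot impute")
    means = np.nansum(codes, axis=0) / n_obs
    idx = np.where(np.isnan(codes))
    codes[idx] = means[idx[1]]
    return GenotypeMatrix(list(g.sample_ids), codes)


def heterozygosity_profiles(
    g: GenotypeMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of heterozygous calls among observed, per individual and per marker."""
    het = g.codes == 1
    obs = ~np.isnan(g.codes)
    with np.errstate(invalid="ignore"):
        per_individual = np.where(
            obs.sum(axis=1) > 0, het.sum(axis=1) / obs.sum(axis=1), np.nan
        )
        per_marker = np.where(
            obs.sum(axis=0) > 0, het.sum(axis=0) / obs.sum(axis=0), np.nan
        )
    return per_individual, per_marker


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a tab-delimited phenotype table (sample id column first).

    A column named ``breed`` (case-insensitive) is treated as the breed
    label; all other non-id columns are traits.  Unparseable trait cells
    become missing (counted in the log).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("phenotype file needs a sample-id column and >=1 trait column")
    id_col = df.columns[0]
    if df[id_col].duplicated().any():
        raise ValueError("duplicate sample IDs in phenotype file")
    df = df.set_index(id_col)
    breed = None
    breed_cols = [c for c in df.columns if c.lower() == "breed"]
    if breed_cols:
        breed = df[breed_cols[0]]
        df = df.drop(columns=breed_cols)
    if df.shape[1] == 0:
        raise ValueError("no trait columns")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    n_bad = int((numeric.isna() & df.notna() & (df != "NA")).sum().sum())
    if n_bad:
        logger.warning("read_phenotypes: %d unparseable cells set to missing", n_bad)
    return PhenotypeTable(numeric, breed)


def write_phenotypes(path: str | Path, p: PhenotypeTable) -> None:
    df = p.data.copy()
    if p.breed is not None:
        df["breed"] = p.breed
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_groups(path: str | Path) -> GroupAssignment:
    """Read a two-column tab-delimited ``sample_id<TAB>group`` file."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("group file needs sample_id and group columns")
    return GroupAssignment(
        pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)
    )


def write_groups(path: str | Path, groups: GroupAssignment) -> None:
    groups.labels.rename("group").to_csv(path, sep="\t", index_label="sample_id")


def assign_breed_means(
    p: PhenotypeTable, breed_of: Mapping[str, str] | None = None
) -> PhenotypeTable:
    """Replace each sample's trait values by its breed's observed means.

    This mirrors the breed-representative phenotyping scheme in which every
    individual of a breed carries the breed's mean measurement.  Explicit
    opt-in: nothing in the pipeline calls this implicitly.
    """
    if breed_of is None:
        if p.breed is None:
            raise ValueError("no breed labels available")
        breed_of = p.breed.to_dict()
    missing = [s for s in p.sample_ids if s not in breed_of]
    if missing:
        raise KeyError(f"samples without a breed label: {missing[:5]}")
    breeds = pd.Series({s: breed_of[s] for s in p.sample_ids})
    out = p.data.copy()
    means = out.groupby(breeds).transform("mean")
    out = means.where(means.notna(), out)
    return PhenotypeTable(out, breeds)


def describe_phenotypes(p: PhenotypeTable) -> pd.DataFrame:
    """Per-trait Max, Min, Mean, SD (sample), SE = SD/sqrt(n), CV% = 100 SD/Mean."""
    rows = {}
    for trait in p.traits:
        v = p.data[trait].dropna()
        if len(v) < 2:
            raise ValueError(f"trait {trait!r} has fewer than 2 observed values")
        sd = v.std(ddof=1)
        mean = v.mean()
        rows[trait] = {
            "Max": v.max(),
            "Min": v.min(),
            "Mean": mean,
            "SD": sd,
            "SE": sd / math.sqrt(len(v)),
            "CV": 100.0 * sd / mean if mean != 0 else np.nan,
        }
    return pd.DataFrame.from_dict(rows, orient="index")[
        ["Max", "Min", "Mean", "SD", "SE", "CV"]
    ]
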