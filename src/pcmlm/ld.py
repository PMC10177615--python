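"""Linkage disequilibrium, decay curves, candidate-gene windows and
genotype-class phenotype summaries.

LD here is the composite (genotypic) r²: the squared Pearson correlation of
unphased ALT dosages over pairwise-complete samples.  Candidate genes are
looked up in a gene annotation within a primary window either side of a
lead SNP (default 20 kb, the characteristic LD-decay distance of the
genome under study) widened to a fallback window (default 100 kb) when the
primary window yields no hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)

GENE_COLUMNS = ["id", "name", "chrom", "start", "end"]


@dataclass
class DecayCurve:
    """Mean r² per physical-distance bin; bins are half-open [lo, hi)."""

    midpoints: np.ndarray
    mean_r2: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mid_bp": self.midpoints, "mean_r2": self.mean_r2, "n_pairs": self.counts}
        )


def genotype_r2(x1: np.ndarray, x2: np.ndarray) -> float:
    """Composite LD: squared dosage correlation over pairwise-complete samples."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("vectors must have equal length")
    ok = ~(np.isnan(x1) | np.isnan(x2))
    a, b = x1[ok], x2[ok]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("vector constant on the pairwise-complete subset")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_decay_curve(
    g: GenotypeMatrix,
    markers: pd.DataFrame,
    max_dist: int,
    bin_width: int,
    subset: Sequence[str] | None = None,
) -> DecayCurve:
    """Mean r² by distance for all intra-chromosomal pairs within max_dist.

    Pair counts per bin sum to the exact number of eligible pairs; pairs
    whose r² is undefined (a locus constant on the complete subset) are
    excluded from both counts and means.
    """
    if not 0 < bin_width < max_dist:
        raise ValueError("need max_dist > bin_width > 0")
    gg = g.take_samples(list(subset)) if subset is not None else g
    edges = np.arange(0, max_dist + bin_width, bin_width)
    n_bins = len(edges) - 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for chrom in pd.unique(markers["chrom"]):
        idx = np.flatnonzero((markers["chrom"] == chrom).to_numpy())
        pos = markers["pos"].to_numpy()[idx]
        order = np.argsort(pos, kind="stable")
        idx, pos = idx[order], pos[order]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                d = pos[b] - pos[a]
                if d > max_dist or d >= edges[-1]:
                    break
                try:
                    r2 = genotype_r2(gg.codes[:, idx[a]], gg.codes[:, idx[b]])
                except ValueError:
                    continue
                k = int(d // bin_width)
                sums[k] += r2
                counts[k] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    mids = edges[:-1] + bin_width / 2.0
    return DecayCurve(mids, means, counts)


def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Extract gene features from a GFF3 file into a table.

    Columns: id, name (may be empty), chrom, start, end (1-based inclusive).
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for gene in db.features_of_type("gene"):
        name = gene.attributes.get("Name", [""])[0]
        rows.append((gene.id, name, gene.seqid, gene.start, gene.end))
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def candidate_genes(
    lead: Mapping,
    annotation: pd.DataFrame,
    primary_window: int = 20_000,
    fallback_window: int = 100_000,
) -> tuple[pd.DataFrame, int]:
    """Genes intersecting [pos − w, pos + w] around a lead SNP.

    Tries the primary window first; when it yields no genes, retries with
    the fallback window.  Intervals are closed, 1-based.  Returns the hit
    table and the window that produced it.
    """
    if not 0 < primary_window <= fallback_window:
        raise ValueError("need 0 < primary_window <= fallback_window")
    chrom, pos = str(lead["chrom"]), int(lead["pos"])
    ann = annotation[annotation["chrom"].astype(str) == chrom]
    if annotation.shape[0] and ann.shape[0] == 0:
        logger.warning("candidate_genes: chromosome %s absent from annotation", chrom)
    for window in (primary_window, fallback_window):
        hits = ann[(ann["start"] <= pos + window) & (ann["end"] >= pos - window)]
        if len(hits):
            return hits.reset_index(drop=True), window
    return ann.iloc[0:0].reset_index(drop=True), fallback_window


def pairwise_r2_near(
    g: GenotypeMatrix,
    markers: pd.DataFrame,
    lead_id: str,
    window: int = 100_000,
) -> pd.DataFrame:
    """r² of every marker within ±window of a lead SNP against the lead."""
    row = markers[markers["id"] == lead_id]
    if row.empty:
        raise KeyError(f"unknown marker {lead_id!r}")
    chrom, pos = row.iloc[0]["chrom"], int(row.iloc[0]["pos"])
    j_lead = int(row.index[0])
    sel = markers[
        (markers["chrom"] == chrom) & (markers["pos"].sub(pos).abs() <= window)
    ]
    out = []
    for j, m in sel.iterrows():
        try:
            r2 = genotype_r2(g.codes[:, j_lead], g.codes[:, int(j)])
        except ValueError:
            r2 = np.nan
        out.append((m["id"], m["chrom"], int(m["pos"]), r2))
    return pd.DataFrame(out, columns=["id", "chrom", "pos", "r2"])


def genotype_phenotype_summary(x: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    """Per observed genotype class: n, mean, median and quartiles of the trait.

    Only classes actually present among complete pairs are reported (a SNP
    with no homozygous-ALT carriers yields two rows, not three).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("genotype and trait vectors must align")
    ok = ~(np.isnan(x) | np.isnan(y))
    if not ok.any():
        raise ValueError("all pairs missing")
    rows = []
    for cls in sorted(set(x[ok])):
        v = y[ok & (x == cls)]
        rows.append(
            {
                "genotype": cls,
                "n": v.size,
                "mean": float(np.mean(v)),
                "q25": float(np.percentile(v, 25)),
                "median": float(np.median(v)),
                "q75": float(np.percentile(v, 75)),
            }
        )
    return pd.DataFrame(rows)
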