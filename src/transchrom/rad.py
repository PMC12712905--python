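"""Region-associated-differential (RAD) spatial enrichment.

Tests whether focal peaks cluster near focal genes' TSSs, per signed-distance
bin, against a genome-wide binomial expectation p0 = M_focal / N_total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import Gene, GenomicInterval
from .normdiff import bh_adjust

__all__ = ["RadConfig", "signed_distance", "build_connections", "rad_enrichment"]


@dataclass(frozen=True)
class RadConfig:
    window_bp: int = 500_000
    bin_width_bp: int = 100_000

    def __post_init__(self) -> None:
        if self.window_bp % self.bin_width_bp != 0:
            raise ValueError("window_bp must be divisible by bin_width_bp")

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(-self.window_bp, self.window_bp + 1, self.bin_width_bp)

    def bin_label(self, i: int) -> str:
        edges = self.bin_edges
        return f"({edges[i]}, {edges[i + 1]}]"

    def bin_index(self, distance: int) -> int:
        """Bin index for a signed distance; bins are (lo, hi] with the first
        bin closed at -window so the full [-window, +window] range is covered.
        A distance of exactly 0 falls in (-bin_width, 0]."""
        if abs(distance) > self.window_bp:
            raise ValueError(f"distance {distance} outside window {self.window_bp}")
        if distance == -self.window_bp:
            return 0
        # (lo, hi] -> ceil division
        return int(np.ceil(distance / self.bin_width_bp)) + self.window_bp // self.bin_width_bp - 1


def signed_distance(gene: Gene, peak: GenomicInterval) -> int:
    """Strand-aware signed distance from TSS to peak midpoint.

    Negative = upstream of the TSS in the direction of transcription,
    positive = downstream. Peak position is its midpoint.
    """
    if gene.chrom != peak.chrom:
        raise ValueError(
            f"signed distance undefined across chromosomes ({gene.chrom} vs {peak.chrom})"
        )
    raw = peak.midpoint - gene.tss
    return raw if gene.strand == "+" else -raw


def build_connections(
    genes: Sequence[Gene],
    peaks: Sequence[GenomicInterval],
    focal_genes: Iterable[str],
    focal_peaks: Iterable[str],
    config: RadConfig = RadConfig(),
) -> pd.DataFrame:
    """All (gene, peak) pairs with |signed distance| <= window.

    ``genes`` is the expressed-gene background (N_total); focal sets must be
    subsets of the supplied backgrounds.
    """
    if not genes:
        raise ValueError("empty gene background")
    focal_genes = set(focal_genes)
    focal_peaks = set(focal_peaks)
    gene_ids = {g.id for g in genes}
    peak_ids = {p.name for p in peaks}
    if not focal_genes <= gene_ids:
        raise ValueError("focal genes not a subset of the gene background")
    if not focal_peaks <= peak_ids:
        raise ValueError("focal peaks not a subset of the peak set")

    # sweep per chromosome on midpoints
    peaks_by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        peaks_by_chrom.setdefault(p.chrom, []).append(p)
    for lst in peaks_by_chrom.values():
        lst.sort(key=lambda p: p.midpoint)

    rows = []
    for gene in genes:
        nearby = peaks_by_chrom.get(gene.chrom, [])
        mids = np.array([p.midpoint for p in nearby])
        if mids.size == 0:
            continue
        lo = np.searchsorted(mids, gene.tss - config.window_bp, side="left")
        hi = np.searchsorted(mids, gene.tss + config.window_bp, side="right")
        for p in nearby[lo:hi]:
            d = signed_distance(gene, p)
            if abs(d) > config.window_bp:
                continue
            rows.append(
                dict(
                    gene_id=gene.id,
                    peak_id=p.name,
                    distance=d,
                    gene_focal=gene.id in focal_genes,
                    peak_focal=p.name in focal_peaks,
                )
            )
    df = pd.DataFrame(rows, columns=["gene_id", "peak_id", "distance", "gene_focal", "peak_focal"])
    df.attrs["n_total_genes"] = len(genes)
    df.attrs["m_focal_genes"] = len(focal_genes)
    return df


def rad_enrichment(
    connections: pd.DataFrame,
    config: RadConfig = RadConfig(),
    n_total_genes: int | None = None,
    m_focal_genes: int | None = None,
) -> pd.DataFrame:
    """Per-bin one-sided binomial enrichment over focal-peak connections.

    Trials n_b = focal-peak connections landing in bin b; successes k_b =
    those whose gene is focal; expectation p0 = M_focal / N_total; BH across
    the bins of this analysis; O/E = (k_b/n_b)/p0.
    """
    n_total = n_total_genes if n_total_genes is not None else connections.attrs.get("n_total_genes")
    m_focal = m_focal_genes if m_focal_genes is not None else connections.attrs.get("m_focal_genes")
    if not n_total:
        raise ValueError("n_total_genes (background size) required and nonzero")
    p0 = m_focal / n_total
    if not 0 < p0 <= 1:
        raise ValueError(f"p0 = {p0} outside (0, 1]")

    focal = connections[connections["peak_focal"]]
    n_bins = len(config.bin_edges) - 1
    n_b = np.zeros(n_bins, dtype=int)
    k_b = np.zeros(n_bins, dtype=int)
    for d, gf in zip(focal["distance"].to_numpy(), focal["gene_focal"].to_numpy()):
        i = config.bin_index(int(d))
        n_b[i] += 1
        if gf:
            k_b[i] += 1

    pvals = np.ones(n_bins)
    oe = np.full(n_bins, np.nan)
    for i in range(n_bins):
        if n_b[i] == 0:
            continue  # p = 1, O/E undefined
        pvals[i] = float(stats.binom.sf(k_b[i] - 1, n_b[i], p0))
        oe[i] = (k_b[i] / n_b[i]) / p0
    qvals = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "bin": [config.bin_label(i) for i in range(n_bins)],
            "n": n_b,
            "k": k_b,
            "p0": p0,
            "pvalue": pvals,
            "qvalue": qvals,
            "oe": oe,
        }
    )
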