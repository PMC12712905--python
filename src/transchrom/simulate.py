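"""Synthetic multi-strain, multi-assay count data with known ground truth.

Emulates a two-parent inbred design (B6, D2) plus an F1 hybrid and a pair of
reciprocal congenic strains that swap the genotype of a single *trans*-acting
master locus. Designated trans-target features carry a dominant repressive
effect driven by the master-locus genotype: H3K9me3 goes up, while
accessibility, H3K27ac, contact (PET) and RNA signal go down. Cis-target
features carry an additive local-allele effect. Counts are negative binomial
around size-factor-scaled expected means, so every downstream statistical
stage can be checked for parameter recovery against the emitted truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    CountMatrix,
    Gene,
    GenomicInterval,
    Interaction,
    SampleSheet,
    write_bed,
    write_bedpe,
    write_counts,
    write_genes,
    write_sample_sheet,
)

ASSAYS = ("ATAC", "H3K27ac", "H3K9me3", "PET", "RNA")
ACTIVE_ASSAYS = ("ATAC", "H3K27ac", "PET", "RNA")

STRAINS = ("B6", "D2", "F1", "B6-13D2", "D2-13B6")

#: master-locus genotype per strain, as allele copies of (B6, D2)
_MASTER_GENOTYPE = {
    "B6": ("B6", "B6"),
    "D2": ("D2", "D2"),
    "F1": ("B6", "D2"),
    "B6-13D2": ("D2", "D2"),
    "D2-13B6": ("B6", "B6"),
}

#: local (background) genotype per strain for features outside the master locus
_LOCAL_GENOTYPE = {
    "B6": ("B6", "B6"),
    "D2": ("D2", "D2"),
    "F1": ("B6", "D2"),
    "B6-13D2": ("B6", "B6"),
    "D2-13B6": ("D2", "D2"),
}


class PlacementError(ValueError):
    """Raised when requested peak placement cannot fit on a chromosome."""


@dataclass(frozen=True)
class SimulationConfig:
    n_chromosomes: int = 2
    chrom_length_bp: int = 50_000_000
    n_genes: int = 300
    n_peaks: int = 2000
    n_interactions: int = 1500
    n_trans_targets: int = 300
    n_cis_targets: int = 300
    n_trans_egenes: int = 20
    frac_d2_repressive: float = 0.84
    delta_k9: float = 2.0
    delta_active: float = 2.0
    d_true: float = -1.0
    cis_beta: float = 2.0
    dispersion: float = 0.05
    replicates_per_strain: int = 3
    baseline_log2_mean: float = 6.5
    baseline_log2_sd: float = 1.0
    library_size: float = 200_000.0
    size_factor_sd: float = 0.15
    rad_window_bp: int = 500_000
    rad_planted_bins: tuple[tuple[int, int], ...] = ((-100_000, 0),)
    frac_short_decoys: float = 0.05
    #: when False, trans-target peaks are placed uniformly (labels and links
    #: are kept but no spatial association is planted) — the RAD null
    plant_spatial: bool = True
    peak_width_bp: int = 1000
    interaction_min_span_bp: int = 20_000
    interaction_max_span_bp: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_d2_repressive <= 1.0:
            raise ValueError("frac_d2_repressive must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.replicates_per_strain < 2:
            raise ValueError("need >= 2 replicates per strain")
        if self.n_peaks < self.n_trans_targets + self.n_cis_targets:
            raise ValueError("n_peaks must cover trans + cis targets")
        if self.delta_k9 < 0 or self.delta_active < 0:
            raise ValueError("effect magnitudes must be non-negative")
        if self.n_trans_egenes > self.n_genes:
            raise ValueError("n_trans_egenes exceeds n_genes")
        for lo, hi in self.rad_planted_bins:
            if hi <= lo:
                raise ValueError(f"degenerate planted bin ({lo}, {hi}]")
            if abs(lo) > self.rad_window_bp or abs(hi) > self.rad_window_bp:
                raise ValueError("planted bin outside RAD window")


@dataclass(frozen=True)
class StrainDesign:
    """Genotype resolution for one strain."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in STRAINS:
            raise ValueError(f"unknown strain {self.name!r}; expected one of {STRAINS}")

    def master_dose(self, allele: str) -> int:
        """Copies of ``allele`` at the master locus (0, 1 or 2)."""
        return _MASTER_GENOTYPE[self.name].count(allele)

    def local_dose(self, allele: str) -> int:
        """Copies of ``allele`` at an ordinary (non-master) locus."""
        return _LOCAL_GENOTYPE[self.name].count(allele)


@dataclass
class GenomeLayout:
    genes: list[Gene]
    peaks: list[GenomicInterval]
    interactions: list[Interaction]
    effects: pd.DataFrame  # feature_id, feature_type, class, repressive_allele, linked_egene, cis_high_allele
    qtl_targets: pd.DataFrame
    config: SimulationConfig
    #: matched-size eGene set with no linked trans-target peaks (RAD control)
    control_egenes: list[str] = field(default_factory=list)

    def effect_row(self, feature_id: str) -> pd.Series:
        return self.effects.loc[feature_id]


def _place_genes(cfg: SimulationConfig, rng: np.random.Generator) -> list[Gene]:
    margin = cfg.rad_window_bp + cfg.peak_width_bp
    if 2 * margin >= cfg.chrom_length_bp:
        raise PlacementError(
            f"RAD window {cfg.rad_window_bp} bp does not fit on "
            f"{cfg.chrom_length_bp} bp chromosomes"
        )
    genes = []
    for i in range(cfg.n_genes):
        chrom = f"chr{rng.integers(1, cfg.n_chromosomes + 1)}"
        tss = int(rng.integers(margin, cfg.chrom_length_bp - margin))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Gene(f"gene_{i:05d}", chrom, tss, strand))
    return genes


def _plant_peak_near(
    gene: Gene, bin_: tuple[int, int], cfg: SimulationConfig, rng: np.random.Generator
) -> GenomicInterval:
    lo, hi = bin_
    signed = int(rng.integers(lo + 1, hi + 1))  # half-open (lo, hi]
    raw = signed if gene.strand == "+" else -signed
    mid = gene.tss + raw
    half = cfg.peak_width_bp // 2
    start, end = mid - half, mid + half
    if start < 0 or end > cfg.chrom_length_bp:
        raise PlacementError(
            f"planted peak [{start}, {end}) outside {gene.chrom} bounds"
        )
    return GenomicInterval(gene.chrom, start, end)


def _pick_separated_egenes(
    genes: Sequence[Gene], cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    min_gap = 2 * cfg.rad_window_bp
    chosen: list[int] = []
    for i in rng.permutation(len(genes)):
        g = genes[i]
        if all(
            g.chrom != genes[j].chrom or abs(g.tss - genes[j].tss) > min_gap
            for j in chosen
        ):
            chosen.append(int(i))
            if len(chosen) == cfg.n_trans_egenes:
                return np.array(chosen)
    raise PlacementError(
        f"cannot place {cfg.n_trans_egenes} eGenes separated by {min_gap} bp; "
        "increase genome size or reduce n_trans_egenes"
    )


def build_genome_layout(cfg: SimulationConfig) -> GenomeLayout:
    """Deterministic (seeded) genome layout with planted effect structure."""
    rng = np.random.default_rng(cfg.seed)
    genes = _place_genes(cfg, rng)

    # trans eGenes: mutually separated by > 2x the RAD window so each eGene's
    # planted peak cluster contributes trials only to its own neighborhood —
    # keeps the per-bin binomial trials independent across eGenes
    egene_idx = _pick_separated_egenes(genes, cfg, rng)
    n_d2_egenes = max(1, round(cfg.frac_d2_repressive * cfg.n_trans_egenes))
    if cfg.frac_d2_repressive == 0.0:
        n_d2_egenes = 0
    if cfg.frac_d2_repressive == 1.0:
        n_d2_egenes = cfg.n_trans_egenes
    d2_egenes = [genes[i] for i in egene_idx[:n_d2_egenes]]
    b6_egenes = [genes[i] for i in egene_idx[n_d2_egenes:]]

    # repressive-allele allocation over trans-target peaks: exact counts
    n_d2 = round(cfg.frac_d2_repressive * cfg.n_trans_targets)
    trans_alleles = np.array(["D2"] * n_d2 + ["B6"] * (cfg.n_trans_targets - n_d2))
    rng.shuffle(trans_alleles)

    peaks: list[GenomicInterval] = []
    records: list[dict] = []
    d2_i = b6_i = 0
    for i in range(cfg.n_trans_targets):
        allele = trans_alleles[i]
        if allele == "D2":
            pool = d2_egenes if d2_egenes else b6_egenes
            gene = pool[d2_i % len(pool)]
            d2_i += 1
        else:
            pool = b6_egenes if b6_egenes else d2_egenes
            gene = pool[b6_i % len(pool)]
            b6_i += 1
        if cfg.plant_spatial:
            bin_ = cfg.rad_planted_bins[i % len(cfg.rad_planted_bins)]
            iv = _plant_peak_near(gene, bin_, cfg, rng)
            iv = GenomicInterval(iv.chrom, iv.start, iv.end, f"peak_{i:05d}")
        else:
            w = cfg.peak_width_bp // 2
            chrom = f"chr{rng.integers(1, cfg.n_chromosomes + 1)}"
            mid = int(rng.integers(w, cfg.chrom_length_bp - w))
            iv = GenomicInterval(chrom, mid - w, mid + w, f"peak_{i:05d}")
        peaks.append(iv)
        records.append(
            dict(
                feature_id=iv.name,
                feature_type="peak",
                cls="trans_target",
                repressive_allele=allele,
                linked_egene=gene.id,
                cis_high_allele="none",
            )
        )

    half = cfg.peak_width_bp // 2
    for i in range(cfg.n_trans_targets, cfg.n_peaks):
        chrom = f"chr{rng.integers(1, cfg.n_chromosomes + 1)}"
        mid = int(rng.integers(half, cfg.chrom_length_bp - half))
        iv = GenomicInterval(chrom, mid - half, mid + half, f"peak_{i:05d}")
        peaks.append(iv)
        if i < cfg.n_trans_targets + cfg.n_cis_targets:
            high = "B6" if rng.random() < 0.5 else "D2"
            records.append(
                dict(
                    feature_id=iv.name,
                    feature_type="peak",
                    cls="cis_target",
                    repressive_allele="none",
                    linked_egene="none",
                    cis_high_allele=high,
                )
            )
        else:
            records.append(
                dict(
                    feature_id=iv.name,
                    feature_type="peak",
                    cls="neutral",
                    repressive_allele="none",
                    linked_egene="none",
                    cis_high_allele="none",
                )
            )

    # interactions: one per trans target and per cis target (anchored on the
    # peak), remainder neutral; an exact count of short decoys (span <= 5 kb)
    interactions: list[Interaction] = []
    n_planted = cfg.n_trans_targets + cfg.n_cis_targets
    n_decoys = round(cfg.frac_short_decoys * cfg.n_interactions)
    if cfg.n_interactions < n_planted + n_decoys:
        raise ValueError("n_interactions too small for planted targets + decoys")

    def _partner(anchor: GenomicInterval, span_lo: int, span_hi: int) -> GenomicInterval:
        d = int(rng.integers(span_lo, span_hi + 1))
        direction = 1 if rng.random() < 0.5 else -1
        mid = anchor.midpoint + direction * d
        mid = min(max(mid, half), cfg.chrom_length_bp - half)
        return GenomicInterval(anchor.chrom, mid - half, mid + half)

    for i in range(n_planted):
        peak = peaks[i]
        other = _partner(peak, cfg.interaction_min_span_bp, cfg.interaction_max_span_bp)
        ixn = Interaction(peak, other, id=f"ixn_{i:05d}")
        interactions.append(ixn)
        src = records[i]
        records.append(
            dict(
                feature_id=ixn.id,
                feature_type="interaction",
                cls=src["cls"],
                repressive_allele=src["repressive_allele"],
                linked_egene=src["linked_egene"],
                cis_high_allele=src["cis_high_allele"],
            )
        )
    for i in range(n_planted, cfg.n_interactions):
        chrom = f"chr{rng.integers(1, cfg.n_chromosomes + 1)}"
        mid = int(rng.integers(half, cfg.chrom_length_bp - half))
        a = GenomicInterval(chrom, mid - half, mid + half)
        if i < n_planted + n_decoys:
            b = _partner(a, cfg.peak_width_bp, 5000 - 1)  # span <= 5 kb decoy
        else:
            b = _partner(a, cfg.interaction_min_span_bp, cfg.interaction_max_span_bp)
        ixn = Interaction(a, b, id=f"ixn_{i:05d}")
        interactions.append(ixn)
        records.append(
            dict(
                feature_id=ixn.id,
                feature_type="interaction",
                cls="neutral",
                repressive_allele="none",
                linked_egene="none",
                cis_high_allele="none",
            )
        )

    # genes: trans eGenes inherit the repression of their linked peaks
    egene_allele = {g.id: "D2" for g in d2_egenes}
    egene_allele.update({g.id: "B6" for g in b6_egenes})
    for gene in genes:
        allele = egene_allele.get(gene.id, "none")
        records.append(
            dict(
                feature_id=gene.id,
                feature_type="gene",
                cls="trans_target" if allele != "none" else "neutral",
                repressive_allele=allele,
                linked_egene=gene.id if allele != "none" else "none",
                cis_high_allele="none",
            )
        )

    effects = pd.DataFrame.from_records(records).set_index("feature_id")
    effects.rename(columns={"cls": "class"}, inplace=True)

    qtl_targets = _build_qtl_targets(peaks, genes, effects, cfg, rng)

    # control eGenes: matched size, non-linked, and genuinely non-proximal —
    # farther than 2x the RAD window from every linked eGene TSS on the same
    # chromosome, so no trans-target peak can fall inside their window
    linked_pos = [(genes[i].chrom, genes[i].tss) for i in egene_idx]

    def _far(g: Gene) -> bool:
        return all(
            g.chrom != c or abs(g.tss - t) > 2 * cfg.rad_window_bp for c, t in linked_pos
        )

    non_linked = [i for i in np.setdiff1d(np.arange(cfg.n_genes), egene_idx) if _far(genes[i])]
    n_ctrl = min(cfg.n_trans_egenes, len(non_linked))
    ctrl_idx = rng.choice(np.array(non_linked, dtype=int), size=n_ctrl, replace=False)
    control_egenes = [genes[i].id for i in ctrl_idx]
    return GenomeLayout(genes, peaks, interactions, effects, qtl_targets, cfg, control_egenes)


def _build_qtl_targets(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[Gene],
    effects: pd.DataFrame,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """QTL-target table in B6-minus-D2 effect orientation."""
    rows = []
    peak_by_id = {p.name: p for p in peaks}
    gene_by_id = {g.id: g for g in genes}
    for fid, row in effects.iterrows():
        if row["class"] == "neutral":
            continue
        if row["feature_type"] == "interaction":
            continue
        lod = float(rng.uniform(5.0, 25.0))
        if row["class"] == "trans_target":
            mode, locus = "trans", "Chr13"
            magnitude = cfg.delta_active
            # D2-repressive: B6 carries the higher (non-repressed) signal
            effect = magnitude if row["repressive_allele"] == "D2" else -magnitude
        else:
            mode, locus = "cis", "local"
            effect = cfg.cis_beta if row["cis_high_allele"] == "B6" else -cfg.cis_beta
        high = "B6" if effect > 0 else "D2"
        if row["feature_type"] == "peak":
            iv = peak_by_id[fid]
            chrom, start, end = iv.chrom, iv.start, iv.end
        else:
            g = gene_by_id[fid]
            chrom, start, end = g.chrom, g.tss, g.tss + 1
        rows.append(
            dict(
                target_id=fid,
                feature_type=row["feature_type"],
                chrom=chrom,
                start=start,
                end=end,
                mode=mode,
                qtl_locus=locus,
                high_allele=high,
                lod=lod,
                effect_size=effect,
            )
        )
    return pd.DataFrame(rows)


def repression_fraction(dose: int, d_true: float) -> float:
    """Fraction of the full repressive effect applied for 0/1/2 allele copies.

    Calibrated so that on the accessibility scale the F1 heterozygote lands at
    midparent + d_true * (high parent - midparent); with d_true = -1 the
    heterozygote equals the repressed homozygote exactly.
    """
    if dose == 2:
        return 1.0
    if dose == 1:
        return (1.0 - d_true) / 2.0
    return 0.0


def expected_log_signal(
    feature_id: str,
    assay: str,
    strain: StrainDesign | str,
    layout: GenomeLayout,
    baseline: float,
) -> float:
    """Expected log2 mean for one (feature, assay, strain) cell."""
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}; expected one of {ASSAYS}")
    if isinstance(strain, str):
        strain = StrainDesign(strain)
    cfg = layout.config
    row = layout.effect_row(feature_id)
    cls = row["class"]
    if cls == "neutral":
        return baseline
    if cls == "cis_target":
        if assay == "H3K9me3":
            return baseline  # cis targets carry no heterochromatin effect
        dose = strain.local_dose(row["cis_high_allele"])
        return baseline + cfg.cis_beta * dose / 2.0
    # trans target
    dose = strain.master_dose(row["repressive_allele"])
    frac = repression_fraction(dose, cfg.d_true)
    if assay == "H3K9me3":
        return baseline + cfg.delta_k9 * frac
    return baseline - cfg.delta_active * frac


@dataclass
class SimulationResult:
    counts: dict[str, CountMatrix]
    sample_sheet: SampleSheet
    truth: pd.DataFrame  # feature_id, assay, strain, expected_log2, class, repressive_allele
    size_factors: pd.DataFrame  # sample, assay, strain, size_factor, depth
    layout: GenomeLayout


def _features_for_assay(layout: GenomeLayout, assay: str) -> list[str]:
    if assay == "PET":
        return [ixn.id for ixn in layout.interactions]
    if assay == "RNA":
        return [g.id for g in layout.genes]
    return [p.name for p in layout.peaks]


def simulate_counts(layout: GenomeLayout) -> SimulationResult:
    """Draw NB counts for every assay/strain/replicate.

    mean = size factor x 2^(expected log2 signal); var = mu + phi mu^2.
    phi = 0 degenerates to Poisson. Per-sample sequencing depth is drawn
    log-normally around ``library_size`` and recorded in the truth output.
    """
    cfg = layout.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))

    sheet_rows = []
    truth_rows = []
    sf_rows = []
    matrices: dict[str, CountMatrix] = {}

    # per-feature baselines are shared across strains/samples within an assay
    for assay in ASSAYS:
        features = _features_for_assay(layout, assay)
        baselines = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, len(features))
        elog2 = np.empty((len(features), len(STRAINS)))
        for j, strain in enumerate(STRAINS):
            design = StrainDesign(strain)
            for i, fid in enumerate(features):
                elog2[i, j] = expected_log_signal(fid, assay, design, layout, baselines[i])

        cols = {}
        for j, strain in enumerate(STRAINS):
            mu_unit = np.exp2(elog2[:, j])
            for rep in range(1, cfg.replicates_per_strain + 1):
                sample = f"{strain}.{assay}.rep{rep}"
                depth = float(
                    cfg.library_size
                    * np.exp(rng.normal(0.0, cfg.size_factor_sd))
                )
                size_factor = depth / mu_unit.sum()
                mu = size_factor * mu_unit
                if cfg.dispersion == 0.0:
                    draws = rng.poisson(mu)
                else:
                    r = 1.0 / cfg.dispersion
                    p = r / (r + mu)
                    draws = rng.negative_binomial(r, p)
                cols[sample] = draws.astype(np.int64)
                sheet_rows.append(dict(sample=sample, strain=strain, assay=assay, replicate=rep))
                sf_rows.append(
                    dict(sample=sample, assay=assay, strain=strain,
                         size_factor=size_factor, depth=depth)
                )
            for i, fid in enumerate(features):
                truth_rows.append(
                    dict(
                        feature_id=fid,
                        assay=assay,
                        strain=strain,
                        expected_log2=elog2[i, j],
                    )
                )
        matrices[assay] = CountMatrix(pd.DataFrame(cols, index=pd.Index(features, name="feature_id")))

    truth = pd.DataFrame(truth_rows)
    eff = layout.effects[["class", "repressive_allele", "linked_egene", "cis_high_allele"]]
    truth = truth.merge(eff, left_on="feature_id", right_index=True, how="left")
    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    return SimulationResult(matrices, sheet, truth, pd.DataFrame(sf_rows), layout)


def simulate(cfg: SimulationConfig) -> SimulationResult:
    """Convenience: layout + counts in one call."""
    return simulate_counts(build_genome_layout(cfg))


def write_outputs(result: SimulationResult, outdir: str | Path) -> dict[str, str]:
    """Write the complete text-format bundle; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = result.layout
    paths: dict[str, str] = {}

    def _reg(name: str, p: Path) -> Path:
        paths[name] = str(p)
        return p

    write_bed(layout.peaks, _reg("peaks_bed", outdir / "peaks.bed"))
    write_genes(layout.genes, _reg("genes_tsv", outdir / "genes.tsv"))
    write_bedpe(layout.interactions, _reg("interactions_bedpe", outdir / "interactions.bedpe"))
    layout.qtl_targets.to_csv(_reg("qtl_targets_tsv", outdir / "qtl_targets.tsv"), sep="\t", index=False)
    _reg("control_egenes", outdir / "control_egenes.txt")
    (outdir / "control_egenes.txt").write_text("\n".join(layout.control_egenes) + "\n")
    layout.effects.to_csv(_reg("effects_tsv", outdir / "effects.tsv"), sep="\t")
    for assay, cm in result.counts.items():
        write_counts(cm, _reg(f"counts_{assay}", outdir / f"counts_{assay}.tsv"))
    write_sample_sheet(result.sample_sheet, _reg("sample_sheet", outdir / "samples.tsv"))
    result.truth.to_csv(_reg("truth_tsv", outdir / "truth.tsv"), sep="\t", index=False)
    result.size_factors.to_csv(_reg("size_factors_tsv", outdir / "size_factors.tsv"), sep="\t", index=False)
    return paths
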