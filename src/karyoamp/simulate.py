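"""Synthetic karyotypes, metaphase panels and paired CNV/RNA matrices.

Every generator returns ground truth alongside its output so downstream
operations can be scored without external files, and no truth field is
computed by the code under test: profiles are built directly from the
sampled parameters, and the ISCN renderer works from those same profiles.

The omics generator plants the "island" motif: a minority of cell lines
jointly high in copy number and expression for a recurrent amplicon gene
set, against a background clustered near the origin with expression linearly
coupled to copy number on the log scales.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .karyotype import (
    CHROMOSOMES,
    CytogeneticProfile,
    KaryotypeRecord,
    MetaphasePanel,
    chrom_sort_key,
)
from .omics import OmicsMatrices

_PLOIDY_BANDS = {
    "near-haploid": (25, 34),
    "near-diploid": (35, 57),
    "near-triploid": (58, 80),
    "near-tetraploid": (81, 103),
    "hyperploid": (104, 150),
}

#: Realistic but unsupported ISCN constructs, used to exercise the
#: unparsed-token accounting.
MALFORMED_TOKENS = ("inc", "r(7)", "ins(5;2)(q13;p13p23)", "idic(15)(q12)", "trc(3;9;11)")


@dataclass
class KaryotypeSimConfig:
    """Study-condition defaults for the karyotype generator: moderate ecDNA
    prevalence, a minority of HSR+ lines, a handful of structural events per
    record, and a small fraction of minimal (low-confidence) records."""

    n_samples: int = 200
    prevalence_ecdna: float = 0.3
    prevalence_hsr: float = 0.15
    aberration_rate: float = 6.0
    detail_dropout: float = 0.1
    explicit_negation_rate: float = 0.05
    malformed_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prevalence_ecdna", "prevalence_hsr", "detail_dropout", "explicit_negation_rate", "malformed_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.aberration_rate < 0 or self.n_samples < 1:
            raise ValueError("aberration_rate must be >= 0 and n_samples >= 1")


@dataclass
class OmicsSimConfig:
    """Paired CNV/RNA generator settings.

    Positive cell lines amplify a recurrent shared amplicon (the island
    motif — e.g. a MYC-like oncogene locus, ``amplicon_genes_per_cell``
    genes shared by all positives) plus ``private_genes_per_cell`` private
    passenger genes unique to each line, drawn ``private_gene_boost`` log2
    units hotter. Amplicon copy number sits well above the quadrant
    threshold with expression coupled linearly; the background clusters
    near the origin.
    """

    n_genes: int = 300
    n_cells: int = 120
    n_positive_cells: int = 12
    amplicon_genes_per_cell: int = 5
    private_genes_per_cell: int = 1
    private_gene_boost: float = 4.0
    amp_cnv_mean: float = 5.0
    amp_cnv_sd: float = 0.6
    background_cnv_sd: float = 0.5
    rna_baseline: float = 2.0
    rna_coupling: float = 1.5
    noise_sd: float = 0.8
    cnv_floor: float = 3.2
    rna_floor: float = 7.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positive_cells > self.n_cells:
            raise ValueError("n_positive_cells cannot exceed n_cells")
        needed = self.amplicon_genes_per_cell + self.private_genes_per_cell * self.n_positive_cells
        if needed > self.n_genes:
            raise ValueError("amplicon + private gene count cannot exceed n_genes")
        if min(self.n_genes, self.n_cells) < 2:
            raise ValueError("matrices need at least 2 genes and 2 cells")


def render_karyotype(profile: CytogeneticProfile, extra_tokens: tuple[str, ...] = ()) -> str:
    """Render a profile back into the ISCN-like grammar the parser accepts."""
    tokens: list[str] = []
    if profile.modal_range is not None:
        tokens.append(f"{profile.modal_range[0]}~{profile.modal_range[1]}")
    elif profile.modal_number is not None:
        tokens.append(str(profile.modal_number))
    if profile.sex_complement:
        tokens.append(profile.sex_complement)
    for chrom in sorted(profile.chrom_gains, key=chrom_sort_key):
        tokens.extend([f"+{chrom}"] * profile.chrom_gains[chrom])
    for chrom in sorted(profile.chrom_losses, key=chrom_sort_key):
        tokens.extend([f"-{chrom}"] * profile.chrom_losses[chrom])
    for fam in ("add", "del", "dup"):
        for chrom in sorted(profile.event_chroms[fam], key=chrom_sort_key):
            tokens.extend([f"{fam}({chrom})"] * profile.event_chroms[fam][chrom])
    for chrom in sorted(profile.event_chroms["iso"], key=chrom_sort_key):
        tokens.extend([f"i({chrom})"] * profile.event_chroms["iso"][chrom])
    for chrom in sorted(profile.derivative_chroms, key=chrom_sort_key):
        tokens.append(f"der({chrom})")
    for a, b in sorted(profile.translocation_chroms, key=lambda p: (chrom_sort_key(p[0]), chrom_sort_key(p[1]))):
        tokens.append(f"t({a};{b})")
    lo, hi = profile.marker_range
    if hi > 0:
        tokens.append(f"{lo}~{hi}mar" if hi > lo else f"{lo}mar")
    if profile.dmin_negated:
        tokens.append("no dmin")
    elif profile.dmin_observed:
        lo, hi = profile.dmin_range
        tokens.append(f"{lo}~{hi}dmin" if hi > lo else ("dmin" if lo == 1 else f"{lo}dmin"))
    if profile.hsr_negated:
        tokens.append("no hsr")
    elif profile.hsr_observed:
        tokens.append("hsr" if profile.hsr_count == 1 else f"{profile.hsr_count}hsr")
    if profile.percent_polyploidy > 0:
        tokens.append(f"{profile.percent_polyploidy}% polyploidy")
    tokens.extend(extra_tokens)
    if not tokens:
        raise ValueError("profile renders to an empty karyotype")
    return ",".join(tokens)


def _sample_modal(rng: np.random.Generator, ploidy_class: str) -> tuple[int | None, tuple[int, int] | None]:
    lo_b, hi_b = _PLOIDY_BANDS[ploidy_class]
    if rng.random() < 0.5:
        lo = int(rng.integers(lo_b, hi_b))
        hi = int(rng.integers(lo, min(hi_b, lo + 8) + 1))
        if hi > lo:
            return None, (lo, hi)
        return lo, None
    return int(rng.integers(lo_b, hi_b + 1)), None


def _sample_profile(rng: np.random.Generator, cfg: KaryotypeSimConfig, ecdna: bool, hsr: bool, minimal: bool) -> tuple[CytogeneticProfile, tuple[str, ...]]:
    classes = np.array(["near-haploid", "near-diploid", "near-triploid", "near-tetraploid", "hyperploid"])
    probs = [0.03, 0.25, 0.40, 0.25, 0.07] if ecdna else [0.03, 0.60, 0.25, 0.10, 0.02]
    ploidy = str(rng.choice(classes, p=probs))
    modal_number, modal_range = _sample_modal(rng, ploidy)
    prof = CytogeneticProfile(modal_number=modal_number, modal_range=modal_range, ploidy_class=ploidy)

    if minimal:
        return prof, ()

    prof.sex_complement = str(rng.choice(["XX", "XY", "X", "XXY", "XXX"], p=[0.35, 0.35, 0.1, 0.1, 0.1]))
    rate = cfg.aberration_rate * (1.6 if ecdna else 1.0)
    n_gain = rng.poisson(rate / 4.0)
    n_loss = rng.poisson(rate / 4.0)
    for _ in range(n_gain):
        c = str(rng.choice(CHROMOSOMES))
        prof.chrom_gains[c] = prof.chrom_gains.get(c, 0) + 1
    for _ in range(n_loss):
        c = str(rng.choice(CHROMOSOMES))
        prof.chrom_losses[c] = prof.chrom_losses.get(c, 0) + 1

    n_events = rng.poisson(rate / 2.0)
    kinds = rng.choice(["add", "del", "dup", "iso", "der", "t"], size=n_events, p=[0.25, 0.25, 0.1, 0.1, 0.15, 0.15])
    for kind in kinds:
        if kind == "der":
            prof.derivative_chroms.add(str(rng.choice(CHROMOSOMES)))
        elif kind == "t":
            a, b = rng.choice(len(CHROMOSOMES), size=2, replace=False)
            pair = tuple(sorted((CHROMOSOMES[a], CHROMOSOMES[b]), key=chrom_sort_key))
            prof.translocation_chroms.add(pair)  # type: ignore[arg-type]
        else:
            prof.event_chroms[kind][str(rng.choice(CHROMOSOMES))] += 1
    prof.structural_variant_total = (
        sum(sum(c.values()) for c in prof.event_chroms.values())
        + len(prof.derivative_chroms)
        + len(prof.translocation_chroms)
    )

    if rng.random() < (0.7 if ecdna else 0.5):
        lo = int(rng.integers(1, 5))
        hi = int(rng.integers(lo, lo + 7))
        prof.marker_range = (lo, hi)
    if rng.random() < 0.4:
        prof.percent_polyploidy = float(round(rng.uniform(1, 30), 1))

    if ecdna:
        lo = int(rng.integers(1, 21))
        hi = int(rng.integers(lo, lo + 81)) if rng.random() < 0.6 else lo
        prof.dmin_range = (lo, hi)
        prof.dmin_observed = True
    elif rng.random() < cfg.explicit_negation_rate:
        prof.dmin_negated = True
    if hsr:
        prof.hsr_count = int(rng.integers(1, 4))
        prof.hsr_observed = True

    extra: list[str] = []
    if rng.random() < 0.2:
        extra.append(f"[cp{int(rng.integers(10, 31))}]")
        prof.composite_count = 1
    if rng.random() < cfg.malformed_rate:
        n_bad = int(rng.integers(1, 3))
        extra.extend(str(rng.choice(MALFORMED_TOKENS)) for _ in range(n_bad))
        prof.unparsed_token_count = n_bad
    return prof, tuple(extra)


def gen_karyotype_records(
    config: KaryotypeSimConfig,
) -> tuple[list[KaryotypeRecord], pd.DataFrame, list[CytogeneticProfile]]:
    """Sample karyotype records with ground truth.

    Returns (records, truth table, truth profiles). The truth table carries
    the underlying ``ecdna_true`` / ``hsr_true`` status (which a minimal
    record may hide from the parser), whether the record is minimal, and
    whether a dmin token was actually rendered.
    """
    rng = np.random.default_rng(config.seed)
    records: list[KaryotypeRecord] = []
    profiles: list[CytogeneticProfile] = []
    rows = []
    for i in range(config.n_samples):
        ecdna = rng.random() < config.prevalence_ecdna
        hsr = rng.random() < config.prevalence_hsr
        minimal = rng.random() < config.detail_dropout
        prof, extra = _sample_profile(rng, config, ecdna, hsr, minimal)
        source = str(rng.choice(["vendor", "literature"], p=[0.7, 0.3]))
        cell_id = f"SYN{i:04d}"
        records.append(
            KaryotypeRecord(
                cell_line_id=cell_id,
                source=source,
                raw_text=render_karyotype(prof, extra),
                validation_source=f"synthetic:{source}",
            )
        )
        profiles.append(prof)
        rows.append(
            {
                "cell_line_id": cell_id,
                "ecdna_true": int(ecdna),
                "hsr_true": int(hsr),
                "minimal_record": bool(minimal),
                "dmin_in_record": bool(prof.dmin_observed),
                "n_malformed": int(prof.unparsed_token_count),
            }
        )
    truth = pd.DataFrame(rows).set_index("cell_line_id")
    return records, truth, profiles


def gen_omics(config: OmicsSimConfig) -> tuple[OmicsMatrices, set[str], dict[str, set[str]]]:
    """Sample paired CNV/RNA matrices with a planted amplicon island.

    All positive cells share one recurrent amplicon gene set (a recurrently
    amplified oncogene locus) and each additionally amplifies private
    passenger genes of its own, drawn hotter — the structure that makes a
    positive line the unique copy-number extreme for some gene. Amplicon
    copy number is a truncated normal with support above ``cnv_floor`` and
    amplicon expression is resampled above ``rna_floor``, so every planted
    point is a quadrant-I point by construction. Returns (matrices,
    positive-cell set, per-cell amplicon gene sets: shared + private).
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{g:04d}" for g in range(config.n_genes)]
    cells = [f"C{c:03d}" for c in range(config.n_cells)]

    cnv = rng.normal(0.0, config.background_cnv_sd, size=(config.n_genes, config.n_cells))
    rna = config.rna_baseline + config.rna_coupling * cnv + rng.normal(0.0, config.noise_sd, size=cnv.shape)

    pos_idx = [int(i) for i in rng.choice(config.n_cells, size=config.n_positive_cells, replace=False)]
    n_private_total = config.private_genes_per_cell * config.n_positive_cells
    special = rng.choice(config.n_genes, size=config.amplicon_genes_per_cell + n_private_total, replace=False)
    shared_idx = [int(g) for g in special[: config.amplicon_genes_per_cell]]
    private_idx = [int(g) for g in special[config.amplicon_genes_per_cell :]]

    def plant(gi: int, ci: int, mean: float) -> None:
        v = rng.normal(mean, config.amp_cnv_sd)
        while v <= config.cnv_floor:
            v = rng.normal(mean, config.amp_cnv_sd)
        cnv[gi, ci] = v
        r = config.rna_baseline + config.rna_coupling * v + rng.normal(0.0, config.noise_sd)
        while r <= config.rna_floor:
            r = config.rna_baseline + config.rna_coupling * v + rng.normal(0.0, config.noise_sd)
        rna[gi, ci] = r

    amplicon: dict[str, set[str]] = {}
    for k, ci in enumerate(pos_idx):
        mine = private_idx[k * config.private_genes_per_cell : (k + 1) * config.private_genes_per_cell]
        for gi in shared_idx:
            plant(gi, ci, config.amp_cnv_mean)
        for gi in mine:
            plant(gi, ci, config.amp_cnv_mean + config.private_gene_boost)
        amplicon[cells[ci]] = {genes[g] for g in shared_idx} | {genes[g] for g in mine}

    rna = np.clip(rna, 0.0, None)
    matrices = OmicsMatrices(
        cnv=pd.DataFrame(cnv, index=genes, columns=cells),
        rna=pd.DataFrame(rna, index=genes, columns=cells),
    )
    return matrices, {cells[i] for i in pos_idx}, amplicon


def gen_metaphase_panels(
    n_panels: int,
    positive_fraction: float,
    seed: int = 0,
    n_images: int = 20,
    min_count: int = 2,
    min_images: int = 2,
) -> tuple[list[MetaphasePanel], list[bool]]:
    """Sample metaphase panels whose truth follows the pathology standard:
    positives have >= ``min_images`` images with >= ``min_count`` ecDNA,
    negatives violate it."""
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError("positive_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    panels: list[MetaphasePanel] = []
    truth: list[bool] = []
    for _ in range(n_panels):
        positive = rng.random() < positive_fraction
        counts = (rng.random(n_images) < 0.3).astype(int)  # background 0/1 noise
        if positive:
            k = int(rng.integers(min_images, n_images + 1))
            hit = rng.choice(n_images, size=k, replace=False)
            counts[hit] = min_count + rng.poisson(4, size=k)
        else:
            if rng.random() < 0.3:  # a lone high image must not flip the call
                counts[rng.integers(n_images)] = min_count + rng.poisson(3)
        panels.append(MetaphasePanel(image_counts=tuple(int(c) for c in counts)))
        truth.append(bool(positive))
    return panels, truth
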