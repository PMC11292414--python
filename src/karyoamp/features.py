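"""Engineering of numeric ML features from cytogenetic profiles.

The 237-column schema expands each profile into scalar features (modal
number/range, ploidy one-hots, sex-complement encodings, marker and
double-minute/HSR summaries, structural-variant totals) plus eight
per-chromosome families (gain, loss, derivative, translocation, add, del,
dup, iso) over chromosomes 1–22, X and Y. Count ranges are expanded to
(min, max, midpoint). The schema is versioned as a YAML file alongside the
package so the reconstruction is explicit and auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .karyotype import CHROMOSOMES, PLOIDY_CLASSES, CytogeneticProfile

_SCALAR_FEATURES: tuple[str, ...] = (
    "modal_number",
    "modal_range_low",
    "modal_range_high",
    "modal_range_mid",
    "modal_range_width",
    "percent_polyploidy",
    *(f"ploidy_{c.replace('-', '_')}" for c in PLOIDY_CLASSES),
    "sex_n_x",
    "sex_n_y",
    "sex_has_y",
    "marker_min",
    "marker_max",
    "marker_mid",
    "marker_present",
    "dmin_min",
    "dmin_max",
    "dmin_mid",
    "dmin_present",
    "hsr_count",
    "hsr_present",
    "sv_total",
    "n_add",
    "n_del",
    "n_der",
    "n_dup",
    "n_t",
    "n_iso",
    "unparsed_tokens",
    "total_gains",
    "total_losses",
    "n_chrom_gained",
    "n_chrom_lost",
    "n_derivative_chroms",
    "n_translocation_chroms",
    "aberration_burden",
    "ploidy_index",
    "sex_total",
    "has_modal_range",
    "composite_count",
    "detail_score",
)

_PER_CHROM_FAMILIES: tuple[str, ...] = ("gain", "loss", "der", "trans", "add", "del", "dup", "iso")


def build_schema() -> list[str]:
    """Deterministic list of the 237 feature column names."""
    cols = list(_SCALAR_FEATURES)
    for fam in _PER_CHROM_FAMILIES:
        cols.extend(f"{fam}_chr{c}" for c in CHROMOSOMES)
    return cols


def load_schema() -> list[str]:
    """Load the versioned schema shipped with the package."""
    text = resources.files("karyoamp.data").joinpath("feature_schema.yaml").read_text()
    doc = yaml.safe_load(text)
    return list(doc["columns"])


FEATURE_SCHEMA: tuple[str, ...] = tuple(build_schema())
N_FEATURES = len(FEATURE_SCHEMA)


@dataclass
class FeatureTable:
    """Samples × engineered-features matrix with per-sample labels.

    ``labels`` carries integer ``ecdna`` / ``hsr`` columns (0/1, NaN when
    unknown) plus a ``provenance`` column so externally merged registry
    records remain distinguishable.
    """

    features: pd.DataFrame
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.features.columns) != list(FEATURE_SCHEMA):
            raise ValueError("feature columns do not match the 237-column schema")
        if not self.features.index.equals(self.labels.index):
            raise ValueError("features and labels must be aligned on sample ids")
        if self.features.index.has_duplicates:
            dupes = self.features.index[self.features.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def sample_ids(self) -> pd.Index:
        return self.features.index

    def subset(self, ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.features.loc[list(ids)], self.labels.loc[list(ids)])


def _range_triplet(rng: tuple[int, int] | None):
    if rng is None:
        return np.nan, np.nan, np.nan
    return float(rng[0]), float(rng[1]), (rng[0] + rng[1]) / 2.0


def profile_to_row(profile: CytogeneticProfile) -> dict[str, float]:
    """Expand one profile into the full scalar feature row."""
    row: dict[str, float] = dict.fromkeys(FEATURE_SCHEMA, 0.0)

    if profile.modal_range is not None:
        lo, hi, mid = _range_triplet(profile.modal_range)
        row["modal_number"] = np.nan  # range-only record; imputed by ploidy later
        row["has_modal_range"] = 1.0
    elif profile.modal_number is not None:
        lo = hi = mid = float(profile.modal_number)
        row["modal_number"] = float(profile.modal_number)
    else:
        lo = hi = mid = np.nan
        row["modal_number"] = np.nan
    row["modal_range_low"], row["modal_range_high"], row["modal_range_mid"] = lo, hi, mid
    row["modal_range_width"] = hi - lo if np.isfinite(hi) else np.nan

    row["percent_polyploidy"] = profile.percent_polyploidy
    row[f"ploidy_{profile.ploidy_class.replace('-', '_')}"] = 1.0
    row["ploidy_index"] = mid / 23.0 if np.isfinite(mid) else np.nan

    row["sex_n_x"] = float(profile.sex_complement.count("X"))
    row["sex_n_y"] = float(profile.sex_complement.count("Y"))
    row["sex_has_y"] = 1.0 if "Y" in profile.sex_complement else 0.0
    row["sex_total"] = row["sex_n_x"] + row["sex_n_y"]

    row["marker_min"], row["marker_max"], row["marker_mid"] = _range_triplet(profile.marker_range)
    row["marker_present"] = 1.0 if profile.marker_range[1] > 0 else 0.0
    row["dmin_min"], row["dmin_max"], row["dmin_mid"] = _range_triplet(profile.dmin_range)
    row["dmin_present"] = 1.0 if profile.dmin_observed and not profile.dmin_negated else 0.0
    row["hsr_count"] = float(profile.hsr_count)
    row["hsr_present"] = 1.0 if profile.hsr_observed and not profile.hsr_negated else 0.0

    ev = profile.event_chroms
    row["n_add"] = float(sum(ev["add"].values()))
    row["n_del"] = float(sum(ev["del"].values()))
    row["n_dup"] = float(sum(ev["dup"].values()))
    row["n_iso"] = float(sum(ev["iso"].values()))
    row["n_der"] = float(len(profile.derivative_chroms))
    row["n_t"] = float(len(profile.translocation_chroms))
    row["sv_total"] = float(profile.structural_variant_total)
    row["unparsed_tokens"] = float(profile.unparsed_token_count)
    row["composite_count"] = float(profile.composite_count)

    row["total_gains"] = float(sum(profile.chrom_gains.values()))
    row["total_losses"] = float(sum(profile.chrom_losses.values()))
    row["n_chrom_gained"] = float(len(profile.chrom_gains))
    row["n_chrom_lost"] = float(len(profile.chrom_losses))
    row["n_derivative_chroms"] = float(len(profile.derivative_chroms))
    row["n_translocation_chroms"] = float(len({c for pair in profile.translocation_chroms for c in pair}))
    row["aberration_burden"] = row["sv_total"] + row["total_gains"] + row["total_losses"]

    detail = sum(
        (
            np.isfinite(mid),
            profile.ploidy_class != "unknown",
            profile.percent_polyploidy > 0,
            bool(profile.sex_complement),
            bool(profile.chrom_gains) or bool(profile.chrom_losses),
            profile.marker_range[1] > 0,
            profile.structural_variant_total > 0,
        )
    )
    row["detail_score"] = float(detail)

    for chrom, count in profile.chrom_gains.items():
        row[f"gain_chr{chrom}"] = float(count)
    for chrom, count in profile.chrom_losses.items():
        row[f"loss_chr{chrom}"] = float(count)
    for chrom in profile.derivative_chroms:
        row[f"der_chr{chrom}"] = 1.0
    for pair in profile.translocation_chroms:
        for chrom in pair:
            row[f"trans_chr{chrom}"] = 1.0
    for fam in ("add", "del", "dup", "iso"):
        for chrom, count in ev[fam].items():
            row[f"{fam}_chr{chrom}"] = float(count)
    return row


def engineer_features(
    profiles: Sequence[CytogeneticProfile],
    sample_ids: Sequence[str],
    ecdna: Sequence[float] | None = None,
    hsr: Sequence[float] | None = None,
    provenance: str = "curated",
) -> FeatureTable:
    """Build the samples × 237 feature table from parsed profiles.

    Labels are 0/1 (NaN for unknown). Duplicate sample ids are rejected.
    """
    if len(profiles) != len(sample_ids):
        raise ValueError("profiles and sample_ids must have equal length")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")
    feats = pd.DataFrame([profile_to_row(p) for p in profiles], index=list(sample_ids))
    feats = feats[list(FEATURE_SCHEMA)]
    labels = pd.DataFrame(
        {
            "ecdna": list(ecdna) if ecdna is not None else np.nan,
            "hsr": list(hsr) if hsr is not None else np.nan,
            "provenance": provenance,
        },
        index=list(sample_ids),
    )
    return FeatureTable(features=feats, labels=labels)


def impute_by_ploidy(table: FeatureTable) -> FeatureTable:
    """Fill missing numeric values with the mean of the sample's ploidy class.

    A sample's class is read off the ploidy one-hot columns; when a class has
    no observed value for a column the global column mean is used. A column
    missing everywhere is an error (nothing to impute from).
    """
    feats = table.features.copy()
    onehot_cols = [f"ploidy_{c.replace('-', '_')}" for c in PLOIDY_CLASSES]
    classes = feats[onehot_cols].idxmax(axis=1)

    for col in feats.columns:
        if not feats[col].isna().any():
            continue
        if feats[col].isna().all():
            raise ValueError(f"column {col!r} is missing for every sample; cannot impute")
        global_mean = feats[col].mean()
        class_means = feats[col].groupby(classes).mean()
        fill = classes.map(class_means).fillna(global_mean)
        feats[col] = feats[col].fillna(fill)
    return FeatureTable(features=feats, labels=table.labels.copy())


def merge_external_records(table: FeatureTable, registry: FeatureTable) -> FeatureTable:
    """Row-wise concatenation of a curated table with external registry
    records (identical schemas required); provenance is retained and
    duplicate sample ids rejected."""
    diff = set(table.features.columns).symmetric_difference(registry.features.columns)
    if diff:
        raise ValueError(f"schema mismatch; differing columns: {sorted(diff)}")
    overlap = table.features.index.intersection(registry.features.index)
    if len(overlap):
        raise ValueError(f"duplicate sample ids across tables: {overlap.tolist()}")
    return FeatureTable(
        features=pd.concat([table.features, registry.features]),
        labels=pd.concat([table.labels, registry.labels]),
    )


def split_train_test(
    table: FeatureTable,
    train_fraction: float = 0.8,
    seed: int = 0,
    stratify_on: tuple[str, ...] = ("ecdna", "hsr"),
) -> tuple[FeatureTable, FeatureTable]:
    """Seed-reproducible stratified train/test partition (disjoint, exhaustive).

    Stratifies on the joint label when every stratum has >= 2 members, falling
    back to the primary label and then to an unstratified split.
    """
    from sklearn.model_selection import train_test_split

    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly in (0, 1)")
    if len(table) < 5:
        raise ValueError("need at least 5 samples to split")

    candidates = [
        table.labels[list(stratify_on)].astype(str).agg("|".join, axis=1),
        table.labels[stratify_on[0]].astype(str),
        None,
    ]
    for strat in candidates:
        if strat is not None and strat.value_counts().min() < 2:
            continue
        train_ids, test_ids = train_test_split(
            table.sample_ids.to_numpy(),
            train_size=train_fraction,
            random_state=seed,
            stratify=None if strat is None else strat.to_numpy(),
        )
        return table.subset(train_ids), table.subset(test_ids)
    raise AssertionError("unreachable")  # pragma: no cover
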