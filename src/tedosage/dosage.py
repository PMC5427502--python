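"""Per-strain TE abundance estimators.

Every estimator used in the association models lives here, on a common
per-average-sequenced-haploid-genome scale:

* ``normalized_coverage`` — mean consensus depth over mean genome depth;
* assembly-based copy numbers — total and full-length copy number and
  per-class proportions from a filtered structural-variant catalog;
* the pseudocount-stabilized full-length/KP coverage ratio;
* annotation-based copy numbers — total insertion count and the
  frequency-weighted copy number from an insertion-caller table.

"Coverage" of a variant is its mean-depth abundance, so dividing by the
genome mean depth yields copies per haploid genome and all estimators
are commensurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variant_model import FULL_LENGTH, KP, OTHER, VariantCatalog

__all__ = [
    "DosageProfile",
    "assembly_copy_numbers",
    "fp_kp_ratio",
    "annotation_copy_numbers",
    "load_annotation_table",
    "build_dosage_matrix",
    "estimator_correlations",
    "ESTIMATOR_COLUMNS",
]

ESTIMATOR_COLUMNS = [
    "normalized_coverage",
    "assembly_total_cn",
    "full_length_cn",
    "prop_full_length",
    "prop_kp",
    "prop_other",
    "fp_kp_ratio",
    "annotation_total",
    "annotation_weighted",
]


@dataclass
class DosageProfile:
    """All abundance estimators for one strain x TE family.

    Estimators that could not be computed are None and stay missing
    (never silently zero) in the dosage matrix.
    """

    strain: str
    family: str
    normalized_coverage: float | None = None
    assembly_total_cn: float | None = None
    full_length_cn: float | None = None
    proportions: dict[str, float] = field(default_factory=dict)
    fp_kp_ratio: float | None = None
    annotation_total: int | None = None
    annotation_weighted: float | None = None

    def as_row(self) -> dict:
        return {
            "strain": self.strain,
            "family": self.family,
            "normalized_coverage": self.normalized_coverage,
            "assembly_total_cn": self.assembly_total_cn,
            "full_length_cn": self.full_length_cn,
            "prop_full_length": self.proportions.get(FULL_LENGTH),
            "prop_kp": self.proportions.get(KP),
            "prop_other": self.proportions.get(OTHER),
            "fp_kp_ratio": self.fp_kp_ratio,
            "annotation_total": self.annotation_total,
            "annotation_weighted": self.annotation_weighted,
        }


def assembly_copy_numbers(
    catalog: VariantCatalog, genome_mean_depth: float
) -> tuple[float, float, dict[str, float], dict[str, float]]:
    """Copy numbers and class proportions from a filtered catalog.

    total_cn = summed variant coverage / genome mean depth;
    full_length_cn likewise for the full-length variant (0 if absent);
    proportions are the coverage fraction per class over retained
    variants (empty when total coverage is 0). Homogeneous of degree 0
    in (abundances, genome depth) jointly.
    """
    if genome_mean_depth <= 0:
        raise ValueError("genome mean depth must be > 0")
    total_abund = catalog.total_abundance
    total_cn = total_abund / genome_mean_depth
    fl_cn = catalog.class_abundance(FULL_LENGTH) / genome_mean_depth
    per_variant = {v.name: v.abundance / genome_mean_depth for v in catalog.retained}
    proportions = (
        {
            cls: catalog.class_abundance(cls) / total_abund
            for cls in (FULL_LENGTH, KP, OTHER)
            if catalog.by_class(cls)
        }
        if total_abund > 0
        else {}
    )
    return total_cn, fl_cn, per_variant, proportions


def fp_kp_ratio(fl_abundance: float, kp_abundance: float, pseudocount: float = 0.01) -> float:
    """(FL + c) / (KP + c): finite, positive ratio of full-length to
    KP-like coverage; the constant keeps zero coverages well-defined."""
    if fl_abundance < 0 or kp_abundance < 0:
        raise ValueError("abundances must be >= 0")
    return (fl_abundance + pseudocount) / (kp_abundance + pseudocount)


def load_annotation_table(path_or_df) -> pd.DataFrame:
    """Read and validate an insertion annotation table.

    Expects columns strain, insertion_id, family, frequency with
    frequencies in (0, 1].
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df, sep="\t")
    required = {"strain", "insertion_id", "family", "frequency"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    freq = df["frequency"].to_numpy(dtype=float)
    if np.any(~np.isfinite(freq)) or np.any(freq <= 0) or np.any(freq > 1):
        raise ValueError("annotation frequencies must be in (0, 1]")
    return df


def annotation_copy_numbers(records: pd.DataFrame, strain: str, family: str) -> tuple[int, float]:
    """Total and frequency-weighted copy number for one strain x family.

    weighted = sum of per-insertion chromosome frequencies, the expected
    copy number per haploid genome; weighted <= total, with equality iff
    all frequencies are 1.
    """
    sub = records[(records["strain"] == strain) & (records["family"] == family)]
    return int(len(sub)), float(sub["frequency"].sum())


def build_dosage_matrix(profiles: list[DosageProfile]) -> pd.DataFrame:
    """Rectangular strain x family table of all estimators.

    Missing estimators are explicit NaN; duplicate strain x family pairs
    are an error.
    """
    rows = [p.as_row() for p in profiles]
    df = pd.DataFrame(rows, columns=["strain", "family"] + ESTIMATOR_COLUMNS)
    dup = df.duplicated(subset=["strain", "family"])
    if dup.any():
        pairs = df.loc[dup, ["strain", "family"]].itertuples(index=False)
        raise ValueError(f"duplicate dosage profiles: {[tuple(t) for t in pairs]}")
    return df


def estimator_correlations(matrix: pd.DataFrame, family: str | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlations across estimators (per family).

    Estimators without variance across strains correlate as NaN
    (reported missing, per the degenerate-variance contract).
    """
    sub = matrix if family is None else matrix[matrix["family"] == family]
    return sub[ESTIMATOR_COLUMNS].astype(float).corr(method="pearson", min_periods=2)
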