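"""mRNA-subtype prototype classification for HNSCC tumours and CAFs.

Tumours (and the CAF cultures derived from them) are assigned to one of
four expression-defined categories — atypical (AT), basal (BA), classical
(CL), mesenchymal (ME) — by a prototype rule: each category is described
by a small signed signature over the marker genes TP63, EGFR, SOX2, VIM,
DES, NFE2L2 plus the binary covariates smoking history and p16 status.
All features are z-scored across the cohort, each category's score is the
mean of its signed standardised features, and the patient is attributed
to the category with the highest score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MARKER_GENES = ("TP63", "EGFR", "SOX2", "VIM", "DES", "NFE2L2")
BINARY_COVARIATES = ("smoking", "p16")
SUBTYPES = ("AT", "BA", "CL", "ME")

#: Signed signature per category: +1 = "high", -1 = "low".
DEFAULT_MARKERS: dict[str, tuple[tuple[str, int], ...]] = {
    "BA": (("TP63", +1), ("EGFR", +1), ("SOX2", -1)),
    "ME": (("VIM", +1), ("DES", +1), ("TP63", -1)),
    "CL": (("SOX2", +1), ("NFE2L2", +1), ("smoking", +1)),
    "AT": (("SOX2", +1), ("p16", +1)),
}

#: Deterministic priority used only to resolve exact score ties.
TIE_PRIORITY = ("AT", "BA", "CL", "ME")

_TIE_EPS = 1e-12


class CohortError(ValueError):
    """Invalid cohort input (missing markers, zero variance, empty)."""


@dataclass
class PatientRecord:
    """One patient's marker expression, covariates and outcome.

    ``expr`` maps gene name to log2 expression and must contain every
    gene in :data:`MARKER_GENES`. ``smoking`` and ``p16`` are 0/1.
    """

    id: str
    expr: Mapping[str, float]
    smoking: int
    p16: int
    clinical: Mapping[str, str] = field(default_factory=dict)
    survival_time: float | None = None
    event: int | None = None

    def __post_init__(self) -> None:
        missing = [g for g in MARKER_GENES if g not in self.expr]
        if missing:
            raise CohortError(
                f"patient {self.id!r}: missing marker gene(s) {missing}"
            )
        for name in BINARY_COVARIATES:
            v = getattr(self, name)
            if v not in (0, 1):
                raise CohortError(
                    f"patient {self.id!r}: {name} must be 0/1, got {v!r}"
                )

    def feature(self, name: str) -> float:
        if name in BINARY_COVARIATES:
            return float(getattr(self, name))
        return float(self.expr[name])


@dataclass
class MarkerSpec:
    """Signed feature lists defining the four subtype prototypes."""

    categories: Mapping[str, Sequence[tuple[str, int]]] = field(
        default_factory=lambda: dict(DEFAULT_MARKERS)
    )

    def __post_init__(self) -> None:
        if set(self.categories) != set(SUBTYPES):
            raise CohortError(
                f"marker spec must define exactly {set(SUBTYPES)}, "
                f"got {set(self.categories)}"
            )
        valid = set(MARKER_GENES) | set(BINARY_COVARIATES)
        for cat, feats in self.categories.items():
            for name, sign in feats:
                if name not in valid:
                    raise CohortError(
                        f"category {cat}: unknown feature {name!r}"
                    )
                if sign not in (+1, -1):
                    raise CohortError(
                        f"category {cat}: sign for {name} must be ±1"
                    )

    @property
    def features(self) -> list[str]:
        seen: list[str] = []
        for feats in self.categories.values():
            for name, _ in feats:
                if name not in seen:
                    seen.append(name)
        return seen


@dataclass
class SubtypeAssignment:
    """Per-category scores and the winning label for one patient."""

    id: str
    scores: dict[str, float]
    label: str
    margin: float
    tied: bool


def standardize_cohort(
    cohort: Sequence[PatientRecord],
    features: Sequence[str] | None = None,
    *,
    standardize_binary: bool = True,
) -> pd.DataFrame:
    """z-score each feature across the cohort (sd with denominator n-1).

    Binary covariates are standardised like expression by default; pass
    ``standardize_binary=False`` to keep them on their raw 0/1 scale
    (the rule's description is ambiguous on this point, so both are
    supported).

    Returns a patients × features DataFrame of z values indexed by
    patient id.

    Raises
    ------
    CohortError
        For cohorts of fewer than two patients or any zero-variance
        feature (the offending feature is named).
    """
    if features is None:
        features = list(MARKER_GENES) + list(BINARY_COVARIATES)
    if len(cohort) < 2:
        raise CohortError("standardisation needs at least 2 patients")
    raw = pd.DataFrame(
        {f: [p.feature(f) for p in cohort] for f in features},
        index=[p.id for p in cohort],
        dtype=float,
    )
    if raw.isna().any().any():
        bad = raw.columns[raw.isna().any()].tolist()
        raise CohortError(f"missing values in feature(s) {bad}")
    z = raw.copy()
    for f in features:
        if not standardize_binary and f in BINARY_COVARIATES:
            continue
        sd = raw[f].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise CohortError(f"feature {f!r} has zero variance in cohort")
        z[f] = (raw[f] - raw[f].mean()) / sd
    return z


def score_subtypes(
    z: Mapping[str, float], spec: MarkerSpec | None = None
) -> dict[str, float]:
    """Score each category as the mean of its signed standardised features."""
    spec = spec or MarkerSpec()
    for name in spec.features:
        if name not in z:
            raise CohortError(f"feature {name!r} absent from standardised data")
    return {
        cat: float(np.mean([sign * z[name] for name, sign in feats]))
        for cat, feats in spec.categories.items()
    }


def assign_subtype(
    scores: Mapping[str, float], patient_id: str = ""
) -> SubtypeAssignment:
    """Pick the highest-scoring category; ties resolved AT > BA > CL > ME.

    ``tied`` is set when the top two scores differ by less than 1e-12.
    """
    vals = np.asarray([scores[c] for c in SUBTYPES], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise CohortError(f"non-finite subtype score for patient {patient_id!r}")
    top = float(vals.max())
    contenders = [c for c in TIE_PRIORITY if top - scores[c] < _TIE_EPS]
    best = contenders[0]
    ordered = sorted((scores[c] for c in SUBTYPES), reverse=True)
    margin = ordered[0] - ordered[1]
    return SubtypeAssignment(
        id=patient_id,
        scores={c: float(scores[c]) for c in SUBTYPES},
        label=best,
        margin=float(margin),
        tied=bool(margin < _TIE_EPS),
    )


def classify_cohort(
    cohort: Sequence[PatientRecord],
    spec: MarkerSpec | None = None,
    *,
    standardize_binary: bool = True,
) -> list[SubtypeAssignment]:
    """standardise → score → assign, for every patient in the cohort."""
    spec = spec or MarkerSpec()
    z = standardize_cohort(cohort, standardize_binary=standardize_binary)
    out = []
    for p in cohort:
        scores = score_subtypes(z.loc[p.id].to_dict(), spec)
        out.append(assign_subtype(scores, p.id))
    return out


def crosstab(
    labels: Sequence[str],
    factor: Sequence[str],
    *,
    label_order: Sequence[str] | None = None,
    factor_order: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tabulate group labels against a clinical factor.

    Returns ``(counts, row_percent)`` with factor levels as rows and
    labels as columns; percentages are per factor level (row) rounded to
    one decimal, the presentation used for clinico-pathological tables.
    """
    if len(labels) == 0:
        raise CohortError("empty cohort")
    if len(labels) != len(factor):
        raise CohortError("labels and factor must be the same length")
    counts = pd.crosstab(
        pd.Series(list(factor), name="factor"),
        pd.Series(list(labels), name="label"),
    )
    if factor_order is not None:
        counts = counts.reindex(index=list(factor_order), fill_value=0)
    if label_order is not None:
        counts = counts.reindex(columns=list(label_order), fill_value=0)
    row_pct = counts.div(counts.sum(axis=1), axis=0).mul(100).round(1)
    return counts, row_pct


def assignments_frame(assignments: Sequence[SubtypeAssignment]) -> pd.DataFrame:
    """Tabulate assignments with per-category score columns."""
    rows = []
    for a in assignments:
        row = {"id": a.id}
        row.update({f"score_{c}": a.scores[c] for c in SUBTYPES})
        row.update({"label": a.label, "margin": a.margin, "tied": a.tied})
        rows.append(row)
    return pd.DataFrame(rows).set_index("id")
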