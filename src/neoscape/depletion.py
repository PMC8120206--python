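"""Neoantigen-depletion and immunogenicity-bias odds-ratio statistics.

Depletion is measured per sample with 2x2 contingency tables comparing
neoantigenic against non-neoantigenic nonsynonymous mutations:

- copy-loss depletion: attribute = "lies in a copy-number-loss region";
  an odds ratio > 1 means neoantigens are preferentially found on lost
  segments (DNA-level depletion);
- transcriptional depletion: attribute = "mutant allele expressed in
  RNA-seq"; an odds ratio < 1 means neoantigen transcripts are
  preferentially reduced.

Zero cells receive the Haldane-Anscombe 0.5 correction (flagged), the 95%
CI is the Woolf logit interval, and the p-value is the two-sided Fisher
exact test on the uncorrected table.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variants import NONSILENT_CLASSES

__all__ = [
    "TwoByTwoTable",
    "OddsRatioResult",
    "DepletionStatus",
    "DepletionCall",
    "build_table",
    "odds_ratio",
    "depletion_call",
    "immunogenicity_bias_or",
    "cohort_depletion_summary",
]

SITE_LABELS = ("PRIMARY", "LYMPH", "DISTANT")


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts: rows = neoantigenic / non-neoantigenic, cols = attribute +/-."""

    a: int  # neoantigenic, attribute present
    b: int  # neoantigenic, attribute absent
    c: int  # non-neoantigenic, attribute present
    d: int  # non-neoantigenic, attribute absent

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.total == 0:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    log_or: float
    ci95: tuple[float, float]
    p_fisher: float
    continuity_corrected: bool


def build_table(
    variants: pd.DataFrame,
    row_predicate: Callable[[pd.Series], bool] | str,
    col_predicate: Callable[[pd.Series], bool] | str,
) -> TwoByTwoTable:
    """Cross-tabulate variants by neoantigenicity x attribute.

    Predicates may be column names (boolean columns) or callables over rows.
    """
    if len(variants) == 0:
        raise ValueError("cannot build a contingency table from zero variants")
    if isinstance(row_predicate, str):
        rows = variants[row_predicate].astype(bool).to_numpy()
    else:
        rows = variants.apply(row_predicate, axis=1).astype(bool).to_numpy()
    if isinstance(col_predicate, str):
        cols = variants[col_predicate].astype(bool).to_numpy()
    else:
        cols = variants.apply(col_predicate, axis=1).astype(bool).to_numpy()
    return TwoByTwoTable(
        a=int(np.sum(rows & cols)),
        b=int(np.sum(rows & ~cols)),
        c=int(np.sum(~rows & cols)),
        d=int(np.sum(~rows & ~cols)),
    )


def odds_ratio(t: TwoByTwoTable, *, z: float = 1.959963984540054) -> OddsRatioResult:
    """Odds ratio (a*d)/(b*c) with Woolf CI and Fisher exact p.

    When any cell is zero, 0.5 is added to every cell before computing the
    OR and CI (Haldane-Anscombe; flagged in the result). The Fisher p is
    always computed on the uncorrected integer table.
    """
    a, b, c, d = (float(x) for x in (t.a, t.b, t.c, t.d))
    corrected = t.has_zero_cell
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    log_or = math.log(or_)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci = (math.exp(log_or - z * se), math.exp(log_or + z * se))
    _, p = stats.fisher_exact(t.as_array(), alternative="two-sided")
    return OddsRatioResult(
        odds_ratio=or_,
        log_or=log_or,
        ci95=ci,
        p_fisher=float(p),
        continuity_corrected=corrected,
    )


class DepletionStatus(str, enum.Enum):
    DEPLETED = "DEPLETED"
    NOT_DEPLETED = "NOT_DEPLETED"
    UNDETERMINED = "UNDETERMINED"


@dataclass(frozen=True)
class DepletionCall:
    sample_id: str
    cnv_loss_or: Optional[OddsRatioResult]
    txn_or: Optional[OddsRatioResult]
    cnv_status: DepletionStatus
    txn_status: DepletionStatus

    @property
    def cnv_depleted(self) -> bool:
        return self.cnv_status is DepletionStatus.DEPLETED

    @property
    def txn_depleted(self) -> bool:
        return self.txn_status is DepletionStatus.DEPLETED


def depletion_call(
    sample_variants: pd.DataFrame,
    sample_id: str = "",
    *,
    significance_gate: bool = False,
    alpha: float = 0.05,
) -> DepletionCall:
    """Per-sample copy-loss and transcriptional depletion calls.

    Expects a variant table with boolean columns ``neoantigenic``,
    ``in_copy_loss`` and ``expressed`` plus ``variant_class``; only
    nonsynonymous mutations enter the tables. Copy-loss depletion is called
    when OR > 1, transcriptional depletion when OR < 1; with
    ``significance_gate`` the Fisher p < alpha is additionally required.
    A sample whose table has an empty neoantigenic or non-neoantigenic row
    is UNDETERMINED.
    """
    nonsyn = sample_variants[
        sample_variants["variant_class"].isin(NONSILENT_CLASSES)
    ]
    n_neo = int(nonsyn["neoantigenic"].astype(bool).sum()) if len(nonsyn) else 0
    n_non = len(nonsyn) - n_neo
    if n_neo == 0 or n_non == 0:
        return DepletionCall(
            sample_id, None, None, DepletionStatus.UNDETERMINED,
            DepletionStatus.UNDETERMINED,
        )
    cnv_or = odds_ratio(build_table(nonsyn, "neoantigenic", "in_copy_loss"))
    txn_or = odds_ratio(build_table(nonsyn, "neoantigenic", "expressed"))

    def gate(res: OddsRatioResult, depleted_direction: bool) -> DepletionStatus:
        if significance_gate and not (res.p_fisher < alpha):
            return DepletionStatus.NOT_DEPLETED
        return (
            DepletionStatus.DEPLETED
            if depleted_direction
            else DepletionStatus.NOT_DEPLETED
        )

    return DepletionCall(
        sample_id=sample_id,
        cnv_loss_or=cnv_or,
        txn_or=txn_or,
        cnv_status=gate(cnv_or, cnv_or.odds_ratio > 1),
        txn_status=gate(txn_or, txn_or.odds_ratio < 1),
    )


def immunogenicity_bias_or(
    reduced: Sequence[bool], increased: Sequence[bool]
) -> OddsRatioResult:
    """Over-representation of immunogenic neoantigens in the REDUCED group.

    Inputs are per-neoantigen booleans for the immunogenicity property
    (strong/medium affinity < 150 nM, or high stability > 2 h) in the reduced
    and increased fate groups. OR > 1 means high-immunogenicity neoantigens
    preferentially land in the reduced group.
    """
    reduced, increased = list(reduced), list(increased)
    if not reduced or not increased:
        raise ValueError("both the reduced and increased groups must be non-empty")
    t = TwoByTwoTable(
        a=sum(bool(x) for x in reduced),
        b=sum(not x for x in reduced),
        c=sum(bool(x) for x in increased),
        d=sum(not x for x in increased),
    )
    return odds_ratio(t)


def cohort_depletion_summary(
    calls: Iterable[DepletionCall], sites: dict[str, str]
) -> pd.DataFrame:
    """Per-site fractions of depleted samples, excluding UNDETERMINED calls.

    ``sites`` maps sample id -> PRIMARY/LYMPH/DISTANT. Sites without any
    determined sample report a missing (NaN) fraction, not 0.
    """
    calls = list(calls)
    for call in calls:
        site = sites.get(call.sample_id)
        if site not in SITE_LABELS:
            raise ValueError(f"unknown site label {site!r} for sample {call.sample_id}")
    rows = []
    for site in SITE_LABELS:
        site_calls = [c for c in calls if sites[c.sample_id] == site]
        for kind in ("cnv", "txn"):
            status = [getattr(c, f"{kind}_status") for c in site_calls]
            det = [s for s in status if s is not DepletionStatus.UNDETERMINED]
            n_dep = sum(1 for s in det if s is DepletionStatus.DEPLETED)
            rows.append(
                {
                    "site": site,
                    "depletion_kind": kind,
                    "n_depleted": n_dep,
                    "n_determined": len(det),
                    "n_undetermined": len(status) - len(det),
                    "fraction_depleted": n_dep / len(det) if det else float("nan"),
                }
            )
    return pd.DataFrame(rows)
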