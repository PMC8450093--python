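"""ChIP/RIP/expression qPCR arithmetic with replicate statistics.

All calculations assume per-cycle doubling (amplification efficiency 2):

* percent input  = 100 * 2^((ct_input - log2(1/fraction_input)) - ct_ip)
* fold change    = case / control (per replicate pairing, then averaged)
* locus ratio    = (locus / reference-locus) per condition, then
  (+treatment) / (-treatment)
* relative expression (delta-delta-Ct) =
  2^-((ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl))

Group comparisons use the two-tailed pooled-variance Student's t-test.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class QpcrError(ValueError):
    pass


def percent_input(ct_ip: float, ct_input: float, fraction_input: float) -> float:
    """ChIP/RIP enrichment as percent of total (dilution-corrected) input."""
    if not 0.0 < fraction_input < 1.0:
        raise QpcrError(f"fraction_input must be in (0, 1), got {fraction_input}")
    if not (math.isfinite(ct_ip) and math.isfinite(ct_input)):
        raise QpcrError("Ct values must be finite")
    return 100.0 * 2.0 ** ((ct_input - math.log2(1.0 / fraction_input)) - ct_ip)


def fold_change_vs_control(enrichment_case: float, enrichment_control: float) -> float:
    if enrichment_control <= 0:
        raise QpcrError(f"control enrichment must be > 0, got {enrichment_control}")
    return enrichment_case / enrichment_control


def locus_ratio_vs_reference(enrichment_locus: float, enrichment_reference: float) -> float:
    """Stage one of the two-stage ChIP normalization: locus over reference
    gene (e.g. eft-3) within one condition."""
    if enrichment_reference <= 0:
        raise QpcrError(f"reference enrichment must be > 0, got {enrichment_reference}")
    return enrichment_locus / enrichment_reference


def treatment_ratio(ratio_plus: float, ratio_minus: float) -> float:
    """Stage two: (+treatment) over (-treatment) of the stage-one ratios."""
    if ratio_minus <= 0:
        raise QpcrError(f"untreated ratio must be > 0, got {ratio_minus}")
    return ratio_plus / ratio_minus


def relative_expression(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Delta-delta-Ct fold change at efficiency 2."""
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)


def t_test_two_tailed(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-tailed pooled-variance (Student's) t-test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise QpcrError("each group needs n >= 2")
    pooled_ss = np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)
    if pooled_ss == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise QpcrError("zero pooled variance with unequal means: t undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Table-level operations


def percent_input_table(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate percent input from a long-format Ct table.

    Input and IP wells are paired by (sample, treatment, locus, replicate).
    """
    required = {"sample", "treatment", "locus", "role", "fraction_input", "replicate", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise QpcrError(f"Ct table missing columns: {sorted(missing)}")
    if ct_table.empty:
        raise QpcrError("empty Ct table")

    keys = ["sample", "treatment", "locus", "replicate"]
    inputs = ct_table[ct_table["role"] == "input"].set_index(keys)
    ips = ct_table[ct_table["role"] == "IP"].set_index(keys)
    common = inputs.index.intersection(ips.index)
    if common.empty:
        raise QpcrError("no paired input/IP wells in Ct table")

    rows = []
    for key in common:
        ct_in = float(inputs.loc[key, "ct"])
        frac = float(inputs.loc[key, "fraction_input"])
        ct_ip = float(ips.loc[key, "ct"])
        rows.append((*key, percent_input(ct_ip, ct_in, frac)))
    return pd.DataFrame(rows, columns=[*keys, "percent_input"])


@dataclass(frozen=True)
class EnrichmentResult:
    """Replicate summary for one comparison."""

    name: str
    case_mean: float
    case_sd: float
    control_mean: float
    control_sd: float
    n: int
    fold_change: float
    fold_change_sd: float | None
    p_value: float

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "case_mean": self.case_mean,
            "case_sd": self.case_sd,
            "control_mean": self.control_mean,
            "control_sd": self.control_sd,
            "n": self.n,
            "fold_change": self.fold_change,
            "fold_change_sd": self.fold_change_sd,
            "p_value": self.p_value,
        }


def _group_values(pct: pd.DataFrame, selector: Mapping[str, str]) -> pd.Series:
    mask = pd.Series(True, index=pct.index)
    for col, val in selector.items():
        if col not in pct.columns:
            raise QpcrError(f"unknown selector column {col!r}")
        mask &= pct[col] == val
    sub = pct[mask].sort_values("replicate")
    if sub.empty:
        raise QpcrError(f"no wells match selector {dict(selector)}")
    return sub.set_index("replicate")["percent_input"]


def summarize(
    pct_table: pd.DataFrame,
    comparisons: Sequence[Mapping],
    fold_method: str = "mean_of_ratios",
) -> list[EnrichmentResult]:
    """Evaluate case-vs-control comparisons on a percent-input table.

    Each comparison is a mapping with keys ``name``, ``case`` and ``control``
    where case/control are column->value selectors.  Fold changes pair
    replicates by index and average the ratios (``mean_of_ratios``; the paper
    legends report mean +/- s.d. of fold changes); ``ratio_of_means`` is the
    alternative.
    """
    if fold_method not in ("mean_of_ratios", "ratio_of_means"):
        raise QpcrError(f"unknown fold_method {fold_method!r}")
    results = []
    for comp in comparisons:
        case = _group_values(pct_table, comp["case"])
        control = _group_values(pct_table, comp["control"])
        if len(case) < 2 or len(control) < 2:
            raise QpcrError(f"comparison {comp.get('name')}: n < 2 replicates")
        if fold_method == "mean_of_ratios":
            common = case.index.intersection(control.index)
            if len(common) < 2:
                raise QpcrError(
                    f"comparison {comp.get('name')}: fewer than 2 paired replicates"
                )
            ratios = (case.loc[common] / control.loc[common]).to_numpy()
            fold = float(np.mean(ratios))
            fold_sd = float(np.std(ratios, ddof=1))
        else:
            fold = fold_change_vs_control(float(case.mean()), float(control.mean()))
            fold_sd = None
        try:
            _, p = t_test_two_tailed(case.to_numpy(), control.to_numpy())
        except QpcrError:
            p = float("nan")  # degenerate zero-variance groups (noise-free runs)
        results.append(
            EnrichmentResult(
                name=str(comp.get("name", "comparison")),
                case_mean=float(case.mean()),
                case_sd=float(case.std(ddof=1)),
                control_mean=float(control.mean()),
                control_sd=float(control.std(ddof=1)),
                n=len(case),
                fold_change=fold,
                fold_change_sd=fold_sd,
                p_value=float(p),
            )
        )
    return results


def write_results(results: Sequence[EnrichmentResult], tsv_path: str | Path) -> None:
    df = pd.DataFrame([r.to_dict() for r in results])
    df.to_csv(tsv_path, sep="\t", index=False)


def load_comparisons(path: str | Path) -> list[dict]:
    with open(path) as fh:
        comps = json.load(fh)
    if not isinstance(comps, list):
        raise QpcrError("comparisons file must contain a JSON list")
    return comps
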