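"""Group summaries, Welch's tests, correlations, and report assembly.

Values are reported as mean ± SEM, matching the reporting convention of
the recordings this package models. Welch's t test (unequal variances,
Satterthwaite degrees of freedom) is the default two-group comparison;
no multiple-testing correction is applied — raw two-sided p values are
reported and the caller chooses a threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import InsufficientDataError, ValidationError
from .hcn import IhResult, ReboundResult, SagResult
from .intrinsic import FiringTypeResult, PassiveProps, RheobaseResult
from .synaptic import JitterResult, TrainResult

FIRING_TYPES = ("T", "F", "S", "U")
EVOKED_TYPES = ("Si", "Multi", "Ba", "Si+Ba", "NR")
PASSIVE_QUANTITIES = ("Cm_pF", "Rm_GOhm", "Vm_rest_mV", "spont_rate_Hz",
                      "rheobase_pA")


@dataclass
class GroupSummary:
    group: str
    quantity: str
    n: int
    mean: float
    sem: float


@dataclass
class TestResult:
    t: float
    df: float
    p: float


@dataclass
class CellAnalysis:
    """Per-cell analysis outputs feeding the group report."""

    cell_id: str
    group: str
    passive: PassiveProps | None = None
    rheobase: RheobaseResult | None = None
    firing: FiringTypeResult | None = None
    ih: IhResult | None = None
    sag: SagResult | None = None
    rebound: ReboundResult | None = None
    evoked_type: str | None = None
    jitter: JitterResult | None = None
    train: TrainResult | None = None


@dataclass
class ReportBundle:
    summaries: pd.DataFrame            # group × quantity: n/mean/SEM
    firing_proportions: pd.DataFrame   # % per firing type, rows sum to 100
    evoked_proportions: pd.DataFrame   # % per evoked type incl. NR
    pairwise_tests: pd.DataFrame       # Welch tests per quantity × group pair
    fold_ratios: pd.DataFrame = field(default_factory=pd.DataFrame)


def summarize_group(values: Sequence[float], group: str = "",
                    quantity: str = "") -> GroupSummary:
    """Mean ± SEM of a set of per-cell values (SEM = SD/sqrt(n), ddof 1)."""
    arr = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("summarize_group needs >=1 finite value")
    sem = float(np.std(arr, ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return GroupSummary(group=group, quantity=quantity, n=int(arr.size),
                        mean=float(np.mean(arr)), sem=sem)


def _as_stats(x) -> tuple[int, float, float]:
    """(n, mean, sd) from raw samples, a GroupSummary, or (n, mean, sem)."""
    if isinstance(x, GroupSummary):
        return x.n, x.mean, x.sem * np.sqrt(x.n)
    if isinstance(x, tuple) and len(x) == 3:
        n, mean, sem = x
        return int(n), float(mean), float(sem) * np.sqrt(n)
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError("welch_test needs n >= 2 per side")
    return int(arr.size), float(np.mean(arr)), float(np.std(arr, ddof=1))


def welch_test(a, b) -> TestResult:
    """Welch's two-sided t test from raw samples or (n, mean, SEM) triples.

    The raw-sample and summary paths agree to floating-point precision
    because Welch's statistic depends on the data only through
    (n, mean, SD). Zero variance on both sides with equal means returns
    t = 0, p = 1 by convention.
    """
    n1, m1, s1 = _as_stats(a)
    n2, m2, s2 = _as_stats(b)
    if s1 == 0.0 and s2 == 0.0:
        if m1 == m2:
            return TestResult(t=0.0, df=float(n1 + n2 - 2), p=1.0)
        return TestResult(t=np.inf if m1 > m2 else -np.inf,
                          df=float(n1 + n2 - 2), p=0.0)
    res = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
    se1, se2 = s1 * s1 / n1, s2 * s2 / n2
    df = (se1 + se2) ** 2 / (se1 ** 2 / (n1 - 1) + se2 ** 2 / (n2 - 1))
    return TestResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient of paired finite values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InsufficientDataError("pearson_r needs paired values, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("pearson_r undefined for zero-variance input")
    return float(sps.pearsonr(x, y).statistic)


def fold_ratio(a, b) -> float:
    """mean(a)/mean(b) — e.g. the capacitance fold-difference between groups."""
    na, ma, _ = _as_stats(a) if not np.isscalar(a) else (1, float(a), 0.0)
    nb, mb, _ = _as_stats(b) if not np.isscalar(b) else (1, float(b), 0.0)
    return ma / mb


def _passive_value(cell: CellAnalysis, quantity: str) -> float:
    if quantity == "rheobase_pA":
        if cell.rheobase is None or not cell.rheobase.excitable:
            return np.nan
        return cell.rheobase.rheobase
    if cell.passive is None:
        return np.nan
    return {
        "Cm_pF": cell.passive.Cm,
        "Rm_GOhm": cell.passive.Rm,
        "Vm_rest_mV": cell.passive.Vm_rest,
        "spont_rate_Hz": cell.passive.spont_rate,
    }[quantity]


def compile_report(cells: Sequence[CellAnalysis]) -> ReportBundle:
    """Assemble group tables and pairwise tests from per-cell results.

    Produces mean ± SEM summaries for the passive quantities and
    rheobase, firing-type and evoked-response-type percentage tables
    (NR included; rows sum to 100 within rounding), pairwise Welch
    tests for each quantity across groups, and capacitance fold-ratios.
    """
    if len(cells) == 0:
        raise InsufficientDataError("compile_report needs >=1 analyzed cell")
    groups = sorted({c.group for c in cells})

    rows = []
    for g in groups:
        gc = [c for c in cells if c.group == g]
        for q in PASSIVE_QUANTITIES:
            vals = [_passive_value(c, q) for c in gc]
            vals = [v for v in vals if np.isfinite(v)]
            if vals:
                s = summarize_group(vals, group=g, quantity=q)
                rows.append({"group": g, "quantity": q, "n": s.n,
                             "mean": s.mean, "sem": s.sem})
    summaries = pd.DataFrame(rows)

    def proportions(label_of, labels):
        prows = []
        for g in groups:
            gl = [label_of(c) for c in cells if c.group == g]
            gl = [x for x in gl if x is not None]
            if not gl:
                continue
            row = {"group": g, "n": len(gl)}
            for lab in labels:
                row[lab] = 100.0 * sum(1 for x in gl if x == lab) / len(gl)
            prows.append(row)
        return pd.DataFrame(prows)

    firing = proportions(
        lambda c: c.firing.label if c.firing is not None else None,
        FIRING_TYPES,
    )
    evoked = proportions(lambda c: c.evoked_type, EVOKED_TYPES)

    trows = []
    if len(groups) >= 2:
        for q in PASSIVE_QUANTITIES:
            for i, g1 in enumerate(groups):
                for g2 in groups[i + 1:]:
                    v1 = [_passive_value(c, q) for c in cells if c.group == g1]
                    v2 = [_passive_value(c, q) for c in cells if c.group == g2]
                    v1 = [v for v in v1 if np.isfinite(v)]
                    v2 = [v for v in v2 if np.isfinite(v)]
                    if len(v1) >= 2 and len(v2) >= 2:
                        r = welch_test(v1, v2)
                        trows.append({"quantity": q, "group_a": g1,
                                      "group_b": g2, "t": r.t, "df": r.df,
                                      "p": r.p})
    tests = pd.DataFrame(trows)

    frows = []
    cm = {r["group"]: r["mean"] for _, r in summaries.iterrows()
          if r["quantity"] == "Cm_pF"}
    for i, g1 in enumerate(groups):
        for g2 in groups:
            if g1 != g2 and g1 in cm and g2 in cm:
                frows.append({"quantity": "Cm_pF", "group_a": g1,
                              "group_b": g2, "fold": cm[g1] / cm[g2]})
    folds = pd.DataFrame(frows)

    return ReportBundle(summaries=summaries, firing_proportions=firing,
                        evoked_proportions=evoked, pairwise_tests=tests,
                        fold_ratios=folds)


def _jsonable(obj):
    import dataclasses
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        obj = obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_cell_analyses(cells: Sequence[CellAnalysis],
                        out_dir: str | Path) -> Path:
    """Write one JSON file per analyzed cell (NaN/inf become null)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cell in cells:
        with open(out / f"{cell.cell_id}.json", "w") as fh:
            json.dump(_jsonable(cell), fh, indent=1, allow_nan=False,
                      default=str)
            fh.write("\n")
    return out


def write_report(bundle: ReportBundle, out_dir: str | Path) -> Path:
    """Write the report as TSV group tables plus a JSON index."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.summaries.to_csv(out / "group_summaries.tsv", sep="\t", index=False)
    bundle.firing_proportions.to_csv(out / "firing_types.tsv", sep="\t", index=False)
    bundle.evoked_proportions.to_csv(out / "evoked_types.tsv", sep="\t", index=False)
    bundle.pairwise_tests.to_csv(out / "pairwise_tests.tsv", sep="\t", index=False)
    bundle.fold_ratios.to_csv(out / "fold_ratios.tsv", sep="\t", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump({
            "tables": ["group_summaries.tsv", "firing_types.tsv",
                       "evoked_types.tsv", "pairwise_tests.tsv",
                       "fold_ratios.tsv"],
        }, fh, indent=1)
    return out
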