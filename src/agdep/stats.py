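"""Discrimination statistics: response tables, GLMMs, exact Wilcoxon.

Builds the per-subject response table from trial summaries and the
design manifest, fits GLMMs with consistency / test-type / order fixed
effects and subject-nested-in-group random intercepts, selects models
by AIC, runs post-hoc single-term GLMMs per test, and computes exact
Wilcoxon signed-rank tests (full sign-permutation null) with effect
sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy import stats as sstats

from .glmm import GLMMResult, fit_glmm_arrays

__all__ = [
    "ModelSpec",
    "WilcoxonResult",
    "build_response_table",
    "fit_glmm",
    "select_model",
    "posthoc_single_term",
    "exact_wilcoxon",
    "effect_size",
    "analyze_response_table",
]

SUBCLASS_CONSISTENCY = {
    "repetition": "consistent",
    "variation": "consistent",
    "missing_first": "inconsistent",
    "missing_last": "inconsistent",
}

_JOIN_KEYS = ["subject_id", "test_type", "trial_index"]


@dataclass(frozen=True)
class ModelSpec:
    """A GLMM specification: response, family and fixed-effect terms.

    ``fixed`` uses patsy term syntax with treatment coding (e.g.
    ``("C(test_type)", "consistency", "C(test_type):consistency")``);
    the intercept is always included.  ``transform_offset`` is added to
    the response before fitting (the +1 shift used for latency).  The
    random structure is fixed by design: random intercepts for group
    and for subject nested within group.
    """

    response: str
    family: str  # gamma | binomial | gaussian
    fixed: tuple[str, ...] = ()
    transform_offset: float = 0.0
    name: str = ""

    @property
    def formula(self) -> str:
        return " + ".join(("1",) + self.fixed)

    @property
    def label(self) -> str:
        return self.name or f"{self.response} ~ {self.formula}"


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+, sum of positive signed ranks
    z: float  # normal approximation (tie-corrected variance)
    exact_p: float  # two-sided, from the full sign-permutation null
    n_pairs: int
    n_nonzero: int
    degenerate: bool  # all differences were zero


def build_response_table(
    summaries: pd.DataFrame, manifest: pd.DataFrame
) -> pd.DataFrame:
    """Aggregate per-trial summaries to subject x test x subclass records.

    ``summaries`` needs the join keys (subject_id, test_type,
    trial_index) plus ``mean_orientation``, ``max_rotation`` and either
    ``n_turns`` or a binary ``turned`` column (and optionally a latency
    column); ``manifest`` supplies subclass, group and order for every
    trial.  Every summary row must join exactly one manifest row.

    Returns one record per subject x test x subclass with the mean of
    trial mean orientations, the max of trial max rotations, the number
    of trials with at least one head turn (``turn_trials`` out of
    ``n_trials``, the Binomial response), the summed turn count, and
    the mean latency of turned trials.  Consistency is derived from the
    subclass.  Trials are conserved: ``n_trials`` sums to the input
    trial count.
    """
    if len(summaries) == 0:
        raise ValueError("no trial summaries provided")
    needed = set(_JOIN_KEYS) | {"mean_orientation", "max_rotation"}
    missing = needed - set(summaries.columns)
    if missing:
        raise ValueError(f"summaries missing columns: {sorted(missing)}")
    merged = summaries.merge(
        manifest, on=_JOIN_KEYS, how="left", suffixes=("", "_manifest"), indicator=True
    )
    orphans = merged[merged["_merge"] != "both"]
    if len(orphans):
        ids = orphans[_JOIN_KEYS].to_dict("records")
        raise ValueError(f"trial summaries with no manifest row: {ids}")
    merged = merged.drop(columns="_merge")
    if "n_turns" in merged.columns:
        merged["_turned"] = (merged["n_turns"] >= 1).astype(int)
        merged["_turn_count"] = merged["n_turns"]
    elif "turned" in merged.columns:
        merged["_turned"] = merged["turned"].astype(int)
        merged["_turn_count"] = merged["_turned"]
    else:
        raise ValueError("summaries need an 'n_turns' or 'turned' column")
    lat_col = next(
        (c for c in ("latency_s", "latency") if c in merged.columns), None
    )
    merged["_latency"] = merged[lat_col] if lat_col else np.nan

    keys = ["subject_id", "group_id", "test_type", "subclass"]
    extra = [c for c in ("subject_order",) if c in merged.columns]
    agg = (
        merged.groupby(keys + extra, as_index=False)
        .agg(
            mean_orientation=("mean_orientation", "mean"),
            max_rotation=("max_rotation", "max"),
            turn_trials=("_turned", "sum"),
            total_turns=("_turn_count", "sum"),
            n_trials=("subject_id", "size"),
            latency=("_latency", "mean"),
        )
    )
    agg["consistency"] = agg["subclass"].map(SUBCLASS_CONSISTENCY)
    if agg["consistency"].isna().any():
        bad = agg.loc[agg["consistency"].isna(), "subclass"].unique()
        raise ValueError(f"unknown stimulus subclasses: {bad.tolist()}")
    return agg


def _design(records: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    dm = dmatrix(spec.formula, records, return_type="dataframe")
    return dm.to_numpy(), list(dm.columns)


def fit_glmm(records: pd.DataFrame, spec: ModelSpec) -> GLMMResult:
    """Fit one GLMM on the response table.

    Random intercepts for social group and subject-within-group are
    always included.  For the binomial family the response is
    ``turn_trials`` successes out of ``n_trials`` (or a binary column
    with one trial each).  Rows with a missing response are dropped
    (latency is undefined for no-turn records).  Non-positive Gamma
    responses raise with the offending records named.
    """
    data = records.copy()
    if spec.response not in data.columns:
        raise ValueError(f"response column {spec.response!r} not in records")
    data["_y"] = data[spec.response] + spec.transform_offset
    data = data[~data["_y"].isna()].reset_index(drop=True)
    if len(data) == 0:
        raise ValueError("no records with a non-missing response")
    X, names = _design(data, spec)
    subj = pd.factorize(data["subject_id"])[0]
    grp = pd.factorize(data["group_id"])[0]
    trials = None
    y = data["_y"].to_numpy(dtype=float)
    if spec.family == "binomial":
        trials = (
            data["n_trials"].to_numpy(dtype=float)
            if "n_trials" in data.columns
            else np.ones(len(data))
        )
    if spec.family == "gamma" and np.any(y <= 0):
        bad = data.loc[y <= 0, [c for c in _JOIN_KEYS if c in data.columns] or None]
        raise ValueError(
            f"Gamma response {spec.response!r} has non-positive values in records:\n"
            f"{bad if bad is not None else np.nonzero(y <= 0)[0].tolist()}"
        )
    return fit_glmm_arrays(
        y, X, names, {"group": grp, "subject": subj}, family=spec.family, trials=trials
    )


def select_model(
    candidates: Sequence[ModelSpec], records: pd.DataFrame
) -> tuple[ModelSpec, pd.DataFrame]:
    """Fit all candidates and pick the lowest-AIC converged model.

    AIC ties break toward fewer parameters; non-converged candidates
    are excluded from selection but kept in the table with a warning
    status.  Returns ``(best_spec, aic_table)``.
    """
    if not candidates:
        raise ValueError("need at least one candidate model")
    rows = []
    fits: list[tuple[ModelSpec, GLMMResult] | None] = []
    for spec in candidates:
        try:
            fit = fit_glmm(records, spec)
        except Exception as exc:  # fit errors surface in the table
            rows.append(
                {"model": spec.label, "aic": np.nan, "n_params": np.nan,
                 "status": f"error: {exc}"}
            )
            fits.append(None)
            continue
        status = "ok" if fit.converged else "not converged"
        if fit.boundary:
            status += "; boundary"
        rows.append(
            {"model": spec.label, "aic": fit.aic, "n_params": fit.n_params,
             "status": status}
        )
        fits.append((spec, fit) if fit.converged else None)
    table = pd.DataFrame(rows)
    usable = [f for f in fits if f is not None]
    if not usable:
        raise ValueError("no candidate model converged")
    for f in fits:
        if f is None and len(usable) < len(fits):
            warnings.warn("one or more candidate models were excluded from AIC selection")
            break
    best_spec, _ = min(usable, key=lambda sf: (round(sf[1].aic, 6), sf[1].n_params))
    return best_spec, table


def posthoc_single_term(
    records: pd.DataFrame,
    response: str,
    term: str,
    subset: pd.Series | str | None = None,
    family: str = "gamma",
    transform_offset: float = 0.0,
) -> GLMMResult:
    """Single-term GLMM on a subset (e.g. consistency within one test)."""
    data = records
    if isinstance(subset, str):
        data = records.query(subset)
    elif subset is not None:
        data = records[subset]
    if len(data) == 0:
        raise ValueError("post-hoc subset is empty")
    bare = term.split("(")[-1].rstrip(")").strip()
    if bare in data.columns and data[bare].nunique() < 2:
        raise ValueError(f"term {term!r} is constant within the subset; no contrast")
    spec = ModelSpec(
        response=response, family=family, fixed=(term,),
        transform_offset=transform_offset,
        name=f"posthoc {response} ~ {term}",
    )
    return fit_glmm(data.reset_index(drop=True), spec)


def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Counts of each W+ value (in half-rank units) over all sign patterns.

    Dynamic-programming convolution of the generating polynomial
    prod_i (1 + x^{2 r_i}); index k of the result counts sign patterns
    with 2*W+ == k.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: len(counts) - r]
        counts = counts + shifted
    return counts


def exact_wilcoxon(x: Sequence[float], y: Sequence[float]) -> WilcoxonResult:
    """Exact Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; ties among the remaining absolute
    differences receive mid-ranks.  The two-sided p-value is computed
    from the full permutation distribution of W+ over all 2^m sign
    assignments of the m non-zero differences (p = 2 * min tail, capped
    at 1), alongside the tie-corrected normal approximation z.  All
    differences zero yields the degenerate result (W+ = 0, p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D samples")
    if len(x) < 1:
        raise ValueError("need at least one pair")
    d = x - y
    nz = d[d != 0]
    m = len(nz)
    if m == 0:
        return WilcoxonResult(0.0, 0.0, 1.0, len(x), 0, True)
    ranks = sstats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    # exact null: all 2^m sign assignments, on mid-ranked values
    ranks2 = np.round(ranks * 2).astype(int)
    counts = _signed_rank_distribution(ranks2)
    total = counts.sum()  # == 2^m
    w2 = int(round(w_plus * 2))
    p_low = counts[: w2 + 1].sum() / total
    p_high = counts[w2:].sum() / total
    exact_p = float(min(1.0, 2.0 * min(p_low, p_high)))
    mean_w = m * (m + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var_w = m * (m + 1) * (2 * m + 1) / 24.0 - np.sum(
        tie_counts**3 - tie_counts
    ) / 48.0
    z = (w_plus - mean_w) / np.sqrt(var_w) if var_w > 0 else 0.0
    return WilcoxonResult(w_plus, float(z), exact_p, len(x), m, False)


def effect_size(z: float, n: int, convention: str = "cohen_d") -> float:
    """Effect size from a test statistic: r = z / sqrt(n), optionally
    converted to Cohen's d = 2r / sqrt(1 - r^2).

    The convention is configurable because reporting practices differ;
    ``"r"`` returns the correlation-style effect size itself.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    r = z / np.sqrt(n)
    if convention == "r":
        return float(r)
    if convention != "cohen_d":
        raise ValueError(f"unknown convention {convention!r}")
    if abs(r) >= 1.0:
        raise ValueError(f"|r| = {abs(r):.3f} >= 1; d is undefined")
    return float(2.0 * r / np.sqrt(1.0 - r**2))


def _candidate_models(response: str, family: str, offset: float = 0.0) -> list[ModelSpec]:
    f = dict(response=response, family=family, transform_offset=offset)
    return [
        ModelSpec(**f, fixed=(), name=f"{response}: intercept only"),
        ModelSpec(**f, fixed=("consistency",), name=f"{response}: consistency"),
        ModelSpec(
            **f, fixed=("consistency", "C(test_type)"),
            name=f"{response}: consistency + test",
        ),
        ModelSpec(
            **f,
            fixed=("consistency", "C(test_type)", "consistency:C(test_type)"),
            name=f"{response}: consistency * test",
        ),
        ModelSpec(
            **f,
            fixed=(
                "consistency", "C(test_type)", "consistency:C(test_type)",
                "C(subject_order)", "consistency:C(subject_order)",
            ),
            name=f"{response}: consistency * test + order * consistency",
        ),
    ]


def analyze_response_table(records: pd.DataFrame) -> dict:
    """Run the full discrimination analysis on a response table.

    For each response variable (mean orientation and maximum rotation,
    Gamma with log link; head-turn indicator, Binomial) candidate GLMMs
    from intercept-only up to consistency x test-type x order structures
    are fitted, the best is selected by AIC, and post-hoc single-term
    consistency GLMMs are run within each test.  Zero values of a Gamma
    response are shifted by +1 degree (with a warning) since the Gamma
    family requires positivity.  Returns a dict per response with the
    AIC table, the selected fit, and the per-test post-hoc fits.
    """
    records = records.copy()
    report: dict[str, dict] = {}
    jobs = [
        ("mean_orientation", "gamma"),
        ("max_rotation", "gamma"),
        ("turn_trials" if "turn_trials" in records.columns else "turned", "binomial"),
    ]
    for response, family in jobs:
        offset = 0.0
        if family == "gamma" and (records[response] <= 0).any():
            offset = 1.0
            warnings.warn(
                f"{response}: non-positive values present; fitting {response}+1"
            )
        best_spec, aic_table = select_model(
            _candidate_models(response, family, offset), records
        )
        best_fit = fit_glmm(records, best_spec)
        posthoc = {}
        for test in sorted(records["test_type"].unique()):
            try:
                posthoc[f"Test{test}"] = posthoc_single_term(
                    records, response, "consistency",
                    subset=f"test_type == {test}", family=family,
                    transform_offset=offset,
                )
            except ValueError as exc:
                posthoc[f"Test{test}"] = str(exc)
        report[response] = {
            "aic_table": aic_table,
            "selected": best_spec,
            "fit": best_fit,
            "posthoc": posthoc,
        }
    return report
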