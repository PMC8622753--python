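"""Best-subset selection for hurdle models under bootstrap out-of-bag scoring.

Workflow (mirroring a repeated-double-resampling pipeline):

1. ``outer_split`` divides the data 3:1 into outer training and validation.
2. From the outer training data, ``b`` bootstrap resamples define inner
   training sets; the out-of-bag (OOB) rows of each resample are the inner
   validation sets (on average a fraction ``1 - (1 - 1/n)^n ~ 1 - 1/e``
   of rows is in-bag).
3. Every non-empty predictor subset (``2^p - 1`` per model part) is fitted
   on each inner training set and scored on the OOB rows with a strictly
   proper scoring rule; for the count part both distributional families are
   fitted and the AIC winner is scored.
4. The subset with the best (smallest) mean OOB score wins and is refitted
   on the full outer training data.

Because the hurdle likelihood separates, the zero-part subset is selected by
a binary score (Brier by default) on all OOB rows and the count-part subset
by a count score (Dawid--Sebastiani by default) on the OOB positives,
independently.  A fully crossed 2^p x 2^p search is not attempted.

The two-stage workflow (claims-only search, cohort-only search, then a joint
search over the union of the two winning subsets) is ``two_stage_join``.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from scipy import special

from .hurdle import (FitError, HurdleSpec, PredictiveDistribution,
                     _check_design, _design_matrix, _fit_logit, fit_hurdle,
                     predict_distribution, select_distribution)
from .scoring import brier_binary, score as score_dist

__all__ = [
    "SearchConfig", "SubsetScore", "BSSResult",
    "outer_split", "enumerate_subsets", "run_bss", "two_stage_join",
]

_MAX_UNCAPPED_P = 25


def outer_split(data: pd.DataFrame, ratio: tuple[int, int] = (3, 1), seed: int = 0,
                n_validation: int | None = None):
    """Seed-reproducible disjoint, exhaustive train/validation split.

    The training share is ``round(n * ratio)``; pass ``n_validation`` to pin
    the validation size explicitly (e.g. to replicate a published 2869/968
    split whose exact rounding rule is not recoverable from a 3:1 ratio).
    """
    n = len(data)
    if n == 0:
        raise ValueError("cannot split empty data")
    if n_validation is None:
        train_n = int(np.floor(n * ratio[0] / (ratio[0] + ratio[1]) + 0.5))
    else:
        train_n = n - int(n_validation)
    train_n = min(max(train_n, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    tr = np.sort(perm[:train_n])
    va = np.sort(perm[train_n:])
    return data.iloc[tr], data.iloc[va]


def enumerate_subsets(p: int, cap: int | None = None):
    """Yield every non-empty predictor subset of ``p`` candidates as a bitmask.

    ``2^p - 1`` subsets in increasing bitmask order; ``cap`` limits subset
    size (number of set bits).  Refuses ``p > 25`` without a cap.
    """
    if p < 1:
        raise ValueError("need at least one candidate")
    if p > _MAX_UNCAPPED_P and cap is None:
        raise ValueError(
            f"p={p} implies 2^{p}-1 subsets; pass max_subset_size to cap the "
            "search or reduce the candidate list")
    for mask in range(1, 2 ** p):
        if cap is None or bin(mask).count("1") <= cap:
            yield mask


def _subset_names(mask: int, names: list[str]) -> tuple[str, ...]:
    return tuple(nm for j, nm in enumerate(names) if mask >> j & 1)


@dataclass
class SearchConfig:
    candidates: list[tuple[str, str]]          # (name, part in {zero, count, both})
    n_bootstrap: int = 500
    outer_split_ratio: tuple[int, int] = (3, 1)
    zero_rule: str = "brier"                   # binary Brier on OOB rows
    count_rule: str = "dawid_sebastiani"       # count score on OOB positives
    seed: int = 0
    max_subset_size: int | None = None
    n_workers: int = 1
    families: tuple[str, ...] = ("poisson", "negbin")

    def __post_init__(self):
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        for name, part in self.candidates:
            if part not in ("zero", "count", "both"):
                raise ValueError(f"candidate {name}: unknown part {part!r}")

    def part_candidates(self, part: str) -> list[str]:
        return [n for n, p in self.candidates if p in (part, "both")]


@dataclass
class SubsetScore:
    part: str
    mask: int
    predictors: tuple[str, ...]
    mean_score: float
    per_bootstrap: np.ndarray
    n_failed_fits: int
    families: tuple[str, ...] = ()   # chosen family per bootstrap (count part)
    disqualified: bool = False


@dataclass
class BSSResult:
    ranking_zero: list[SubsetScore]
    ranking_count: list[SubsetScore]
    best_spec: HurdleSpec
    final_fit: object
    provenance: dict
    intercept_only: dict = field(default_factory=dict)

    @property
    def best_zero(self) -> SubsetScore:
        return self.ranking_zero[0]

    @property
    def best_count(self) -> SubsetScore:
        return self.ranking_count[0]


def _score_zero_subset(mask, names, design, z, boots, rule):
    """Mean OOB binary score of one zero-part subset over all bootstraps."""
    preds = _subset_names(mask, names)
    X = _design_matrix(design, preds)
    scores = np.full(len(boots), np.nan)
    try:
        _check_design(X, ["intercept", *preds])
    except FitError:
        return preds, scores
    for j, (inb, oob) in enumerate(boots):
        z_in = z[inb]
        if z_in.all() or not z_in.any():
            continue
        try:
            beta, _, _, _ = _fit_logit(X[inb], z_in)
        except FitError:
            continue
        pi = special.expit(np.clip(X[oob] @ beta, -30, 30))
        scores[j] = brier_binary(pi, z[oob]).mean
    return preds, scores


def _score_count_subset(mask, names, design, y, boots, rule, families):
    preds = _subset_names(mask, names)
    scores = np.full(len(boots), np.nan)
    fams = []
    for j, (inb, oob) in enumerate(boots):
        y_in = y[inb]
        y_oob = y[oob]
        pos_oob = y_oob > 0
        if (y_in > 0).sum() < len(preds) + 2 or pos_oob.sum() == 0:
            fams.append("none")
            continue
        try:
            if len(families) == 2:
                fam, fit_p, fit_nb = select_distribution(
                    design.iloc[inb], y_in,
                    HurdleSpec((), preds, "poisson"), HurdleSpec((), preds, "negbin"))
                fit = fit_p if fam == "poisson" else fit_nb
            else:
                fam = families[0]
                fit = fit_hurdle(design.iloc[inb], y_in, HurdleSpec((), preds, fam))
            oob_pos_design = design.iloc[oob].loc[np.asarray(pos_oob)]
            dist = predict_distribution(fit, oob_pos_design,
                                        k_max=max(int(y.max()) + 20, 30))
            # score the truncated count forecast: renormalise to positives
            trunc = dist.pmf[:, 1:] / dist.p_positive[:, None]
            mean_t = dist.mean / dist.p_positive
            var_t = np.maximum(
                (dist.sd ** 2 + dist.mean ** 2) / dist.p_positive - mean_t ** 2, 1e-12)
            tdist = PredictiveDistribution(
                p_positive=np.ones(len(mean_t)),
                pmf=np.column_stack([np.zeros(len(mean_t)), trunc]),
                mean=mean_t, sd=np.sqrt(var_t), k_max=dist.k_max)
            scores[j] = score_dist(tdist, y_oob[pos_oob], _rule_key(rule)).mean
            fams.append(fam)
        except FitError:
            fams.append("failed")
            continue
    return preds, scores, tuple(fams)


def _rule_key(rule: str) -> str:
    aliases = {"dss": "dawid_sebastiani", "brier": "quadratic_brier",
               "log": "logarithmic", "rps": "ranked_probability"}
    return aliases.get(rule, rule)


def _rank(entries: list[SubsetScore]) -> list[SubsetScore]:
    eligible = [e for e in entries if not e.disqualified]
    rest = [e for e in entries if e.disqualified]
    eligible.sort(key=lambda e: (e.mean_score, e.mask))
    return eligible + rest


def run_bss(data: pd.DataFrame, outcome: str, config: SearchConfig) -> BSSResult:
    """Exhaustive part-wise best-subset search with bootstrap OOB scoring.

    *data* must contain the outcome column and every candidate column with
    no missing cells (impute upstream).  Returns rankings per part, the
    winning specification and its refit on the full data passed in.
    """
    t0 = time.time()
    y = data[outcome].to_numpy(int)
    design = data.drop(columns=[outcome])
    z = (y > 0).astype(float)
    n = len(data)
    rng = np.random.default_rng(config.seed)
    boots = []
    for _ in range(config.n_bootstrap):
        inb = np.sort(rng.integers(0, n, n))
        oob = np.setdiff1d(np.arange(n), inb)
        boots.append((inb, oob))

    zero_names = config.part_candidates("zero")
    count_names = config.part_candidates("count")
    n_subsets = {
        "zero": (2 ** len(zero_names) - 1) if zero_names else 0,
        "count": (2 ** len(count_names) - 1) if count_names else 0,
    }

    parallel = Parallel(n_jobs=config.n_workers, prefer="processes") \
        if config.n_workers > 1 else None

    def collect_zero():
        masks = list(enumerate_subsets(len(zero_names), config.max_subset_size)) \
            if zero_names else []
        work = (delayed(_score_zero_subset)(m, zero_names, design, z, boots,
                                            config.zero_rule) for m in masks)
        outs = parallel(work) if parallel else [
            _score_zero_subset(m, zero_names, design, z, boots, config.zero_rule)
            for m in masks]
        entries = []
        for mask, (preds, scores) in zip(masks, outs):
            ok = ~np.isnan(scores)
            entries.append(SubsetScore(
                part="zero", mask=mask, predictors=preds,
                mean_score=float(scores[ok].mean()) if ok.any() else np.inf,
                per_bootstrap=scores, n_failed_fits=int((~ok).sum()),
                disqualified=(~ok).mean() > 0.5))
        return entries

    def collect_count():
        masks = list(enumerate_subsets(len(count_names), config.max_subset_size)) \
            if count_names else []
        work = (delayed(_score_count_subset)(m, count_names, design, y, boots,
                                             config.count_rule, config.families)
                for m in masks)
        outs = parallel(work) if parallel else [
            _score_count_subset(m, count_names, design, y, boots,
                                config.count_rule, config.families)
            for m in masks]
        entries = []
        for mask, (preds, scores, fams) in zip(masks, outs):
            ok = ~np.isnan(scores)
            entries.append(SubsetScore(
                part="count", mask=mask, predictors=preds,
                mean_score=float(scores[ok].mean()) if ok.any() else np.inf,
                per_bootstrap=scores, n_failed_fits=int((~ok).sum()),
                families=fams, disqualified=(~ok).mean() > 0.5))
        return entries

    ranking_zero = _rank(collect_zero())
    ranking_count = _rank(collect_count())

    def best_eligible(ranking):
        for e in ranking:
            if not e.disqualified:
                return e.predictors
        return ()   # every subset disqualified: fall back to intercept-only

    best_zero = best_eligible(ranking_zero)
    best_count = best_eligible(ranking_count)

    # intercept-only reference scores (dominance sanity)
    _, s0 = _score_zero_subset(0, [], design, z, boots, config.zero_rule)
    ref = {"zero": float(np.nanmean(s0))}
    _, sc0, _ = _score_count_subset(0, [], design, y, boots, config.count_rule,
                                    config.families)
    ref["count"] = float(np.nanmean(sc0)) if np.any(~np.isnan(sc0)) else np.inf

    family = "poisson"
    if ranking_count and len(config.families) == 2:
        winner = next((e for e in ranking_count if e.predictors == best_count), None)
        fams = [f for f in (winner.families if winner else ())
                if f in ("poisson", "negbin")]
        if fams and sum(f == "negbin" for f in fams) > len(fams) / 2:
            family = "negbin"
    spec = HurdleSpec(best_zero, best_count, family)
    final_fit = fit_hurdle(design, y, spec)

    provenance = {"seed": config.seed, "n_bootstrap": config.n_bootstrap,
                  "n_rows": n, "n_subsets": n_subsets,
                  "mean_oob_fraction": float(np.mean([len(o) / n for _, o in boots])),
                  "runtime_s": round(time.time() - t0, 3)}
    return BSSResult(ranking_zero=ranking_zero, ranking_count=ranking_count,
                     best_spec=spec, final_fit=final_fit, provenance=provenance,
                     intercept_only=ref)


def two_stage_join(claims_result: BSSResult, cohort_result: BSSResult,
                   joined_data: pd.DataFrame, outcome: str,
                   config: SearchConfig) -> tuple[BSSResult, pd.DataFrame]:
    """Second-stage search over the union of two first-stage winning subsets.

    Returns the joint :class:`BSSResult` plus a provenance table stating for
    every candidate (and every selected predictor) which stage it came from.
    """
    pool: list[tuple[str, str]] = []
    origin: dict[str, set] = {}
    for src, res in (("claims", claims_result), ("cohort", cohort_result)):
        for part, preds in (("zero", res.best_spec.zero_part_predictors),
                            ("count", res.best_spec.count_part_predictors)):
            for name in preds:
                origin.setdefault(name, set()).add(src)
                if (name, part) not in pool:
                    pool.append((name, part))
    if not pool:
        raise ValueError("both stage-one best subsets are empty; nothing to join")
    merged: dict[str, str] = {}
    for name, part in pool:
        if name not in merged:
            merged[name] = part
        elif merged[name] != part:
            merged[name] = "both"
    candidates = sorted(merged.items())
    cfg2 = SearchConfig(candidates=candidates, n_bootstrap=config.n_bootstrap,
                        outer_split_ratio=config.outer_split_ratio,
                        zero_rule=config.zero_rule, count_rule=config.count_rule,
                        seed=config.seed, max_subset_size=config.max_subset_size,
                        n_workers=config.n_workers, families=config.families)
    result = run_bss(joined_data, outcome, cfg2)
    selected = set(result.best_spec.zero_part_predictors) \
        | set(result.best_spec.count_part_predictors)
    prov = pd.DataFrame([
        {"predictor": name, "stage_origin": "+".join(sorted(origin[name])),
         "selected": name in selected}
        for name, _ in candidates])
    return result, prov
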