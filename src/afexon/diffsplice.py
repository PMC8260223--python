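"""Differential splicing by two routes: per-candidate t-tests on PSI and a
per-event Dirichlet-multinomial likelihood-ratio test.

The DM model treats each sample's candidate-count vector y (total n) as
DM(n; pi, phi) with proportions pi and precision phi; phi -> infinity
recovers the multinomial.  The LRT compares condition-specific proportions
against shared proportions at a common precision, with an asymptotic
chi-square null on (conditions-1)*(candidates-1) degrees of freedom.

With few replicates a per-event precision estimate is too noisy for the
chi-square reference to hold, so the default test shares one precision
across all tested events, estimated by maximizing the summed Cox-Reid
adjusted profile likelihood under the full (per-condition) design — the
same moderation idea the Dirichlet-multinomial differential-usage tools
use.  A fixed precision can be supplied instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .core import ValidationError, bh_adjust
from .events import ASEvent, PsiTable

log = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "event_id",
    "candidate",
    "candidate_index",
    "event_type",
    "novelty",
    "gene_id",
    "mean_psi_control",
    "mean_psi_treated",
    "delta_psi",
    "p_raw",
    "p_adj",
    "test",
    "significant",
]


# ---------------------------------------------------------------------------
# t-test route


def ttest_diff(
    psi: PsiTable,
    control: str = "control",
    treated: str = "LPS",
    delta_thresh: float = 5.0,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sample t-test on per-sample PSI, candidate by candidate.

    Candidates whose |delta PSI| falls below ``delta_thresh`` are not
    tested (no p-value assigned); BH runs over the assigned p-values only.
    The default is the pooled-variance test; ``equal_var=False`` switches
    to Welch.  delta PSI is mean(treated) - mean(control).
    """
    ctrl_cols = psi.samples_of(control)
    trt_cols = psi.samples_of(treated)
    rows = []
    for rid, meta in psi.meta.iterrows():
        c = psi.psi.loc[rid, ctrl_cols].dropna().to_numpy(dtype=float)
        t = psi.psi.loc[rid, trt_cols].dropna().to_numpy(dtype=float)
        rec = {
            "event_id": meta["event_id"],
            "candidate": meta["candidate"],
            "candidate_index": meta["candidate_index"],
            "event_type": meta["event_type"],
            "novelty": meta["novelty"],
            "gene_id": meta["gene_id"],
            "mean_psi_control": c.mean() if c.size else np.nan,
            "mean_psi_treated": t.mean() if t.size else np.nan,
            "p_raw": np.nan,
            "test": "ttest",
        }
        rec["delta_psi"] = rec["mean_psi_treated"] - rec["mean_psi_control"]
        if c.size >= 2 and t.size >= 2 and abs(rec["delta_psi"]) >= delta_thresh:
            if np.ptp(c) == 0 and np.ptp(t) == 0:
                # zero within-group variance with a real difference
                rec["p_raw"] = 0.0 if rec["delta_psi"] != 0 else np.nan
            else:
                rec["p_raw"] = stats.ttest_ind(t, c, equal_var=equal_var).pvalue
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_raw"])
    out["significant"] = False
    return out[RESULT_COLUMNS]


# ---------------------------------------------------------------------------
# Dirichlet-multinomial route


def dm_loglik(counts: np.ndarray, pi: np.ndarray, phi: float) -> float:
    """Dirichlet-multinomial log-likelihood of an S x K count matrix.

    Includes the multinomial coefficient; computed with log-gamma
    throughout.  A category with pi_j = 0 but positive counts yields -inf.
    """
    y = np.atleast_2d(np.asarray(counts, dtype=float))
    pi = np.asarray(pi, dtype=float)
    if phi <= 0:
        raise ValidationError("phi must be > 0")
    if (pi < 0).any() or abs(pi.sum() - 1.0) > 1e-8:
        raise ValidationError("pi must be a probability vector")
    if y.shape[0] == 0:
        return 0.0
    n = y.sum(axis=1)
    zero = pi == 0
    if zero.any() and (y[:, zero] > 0).any():
        return float("-inf")
    keep = ~zero
    yk = y[:, keep]
    alpha = phi * pi[keep]
    ll = (
        gammaln(n + 1).sum()
        - gammaln(y + 1).sum()
        + y.shape[0] * gammaln(phi)
        - gammaln(n + phi).sum()
        + gammaln(yk + alpha).sum()
        - yk.shape[0] * gammaln(alpha).sum()
    )
    return float(ll)


def _fit_pi(y: np.ndarray, phi: float, tol: float = 1e-9, max_iter: int = 100) -> np.ndarray:
    """MLE of DM proportions at fixed precision by a fixed-point sweep.

    Minka-type update on alpha = phi*pi with the total constrained to phi
    (renormalised each sweep); initialised at the pooled count proportions.
    """
    from scipy.special import digamma

    y = np.atleast_2d(np.asarray(y, dtype=float))
    tot = y.sum(axis=0)
    if tot.sum() == 0:
        raise ValidationError("all-zero counts")
    pi = (tot + 0.5) / (tot + 0.5).sum()
    for _ in range(max_iter):
        alpha = phi * pi
        num = (digamma(y + alpha) - digamma(alpha)).sum(axis=0)
        w = pi * num
        new = w / w.sum() if w.sum() > 0 else pi
        if np.abs(new - pi).max() < tol:
            pi = new
            break
        pi = new
    return pi


@dataclass
class DMFit:
    pi_by_condition: dict[str, np.ndarray]
    pi_null: np.ndarray
    phi: float
    ll_alt: float
    ll_null: float
    lrt_stat: float
    df: int


_PHI_GRID = np.exp(np.linspace(np.log(0.5), np.log(5e4), 18))


def _profile_ll(groups: Sequence[np.ndarray], phi: float) -> tuple[float, list[np.ndarray]]:
    pis = [_fit_pi(y, phi) for y in groups]
    ll = sum(dm_loglik(y, pi, phi) for y, pi in zip(groups, pis))
    return ll, pis


def _golden_max(fn, lo: float, hi: float, tol: float = 1e-3, max_iter: int = 25):
    """Golden-section maximization of fn over [lo, hi] (log-phi scale)."""
    gr = (np.sqrt(5.0) - 1) / 2
    a, b = lo, hi
    c1 = b - gr * (b - a)
    c2 = a + gr * (b - a)
    f1, f2 = fn(c1), fn(c2)
    for _ in range(max_iter):
        if b - a < tol:
            break
        if f1 < f2:
            a, c1, f1 = c1, c2, f2
            c2 = a + gr * (b - a)
            f2 = fn(c2)
        else:
            b, c2, f2 = c2, c1, f1
            c1 = b - gr * (b - a)
            f1 = fn(c1)
    return (a + b) / 2


def _maximize_over_phi(fn) -> float:
    """Grid + golden-section maximization of fn(phi) on the log-phi scale."""
    lls = [fn(float(phi)) for phi in _PHI_GRID]
    best = int(np.argmax(lls))
    lo = np.log(_PHI_GRID[max(best - 1, 0)])
    hi = np.log(_PHI_GRID[min(best + 1, len(_PHI_GRID) - 1)])
    x = _golden_max(lambda lg: fn(float(np.exp(lg))), lo, hi)
    return float(np.exp(x))


def dm_fit(
    counts_by_condition: Mapping[str, np.ndarray], phi: Optional[float] = None
) -> DMFit:
    """Fit the DM model under alternative (per-condition pi) and null (shared pi).

    One precision phi is shared across conditions: profiled on a log grid and
    refined by golden-section search under the alternative (unless supplied),
    then reused for the null so the models are nested at a common phi.
    """
    conds = list(counts_by_condition)
    groups = [np.atleast_2d(np.asarray(counts_by_condition[c], dtype=float)) for c in conds]
    for c, y in zip(conds, groups):
        if y.sum() == 0:
            raise ValidationError(f"condition {c} has all-zero counts")
    k = groups[0].shape[1]

    phi_hat = float(phi) if phi is not None else _maximize_over_phi(
        lambda f: _profile_ll(groups, f)[0]
    )
    ll_alt, pis = _profile_ll(groups, phi_hat)
    pooled = np.vstack(groups)
    pi_null = _fit_pi(pooled, phi_hat)
    ll_null = dm_loglik(pooled, pi_null, phi_hat)
    lrt = max(0.0, 2.0 * (ll_alt - ll_null))
    return DMFit(
        pi_by_condition={c: p for c, p in zip(conds, pis)},
        pi_null=pi_null,
        phi=phi_hat,
        ll_alt=float(ll_alt),
        ll_null=float(ll_null),
        lrt_stat=float(lrt),
        df=(len(conds) - 1) * (k - 1),
    )


def _ll_simplex(y: np.ndarray, theta: np.ndarray, phi: float) -> float:
    pi = np.append(theta, 1.0 - theta.sum())
    if (pi <= 0).any():
        return float("-inf")
    return dm_loglik(y, pi, phi)


def _cr_adjustment(y: np.ndarray, pi: np.ndarray, phi: float, h: float = 1e-5) -> float:
    """Cox-Reid term: 0.5*log det of the negative Hessian over the free
    proportion coordinates, by central finite differences."""
    theta = np.asarray(pi[:-1], dtype=float)
    k = theta.size
    hess = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            fpp = _ll_simplex(y, theta + ei + ej, phi)
            fpm = _ll_simplex(y, theta + ei - ej, phi)
            fmp = _ll_simplex(y, theta - ei + ej, phi)
            fmm = _ll_simplex(y, theta - ei - ej, phi)
            if not all(np.isfinite(v) for v in (fpp, fpm, fmp, fmm)):
                return 0.0
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    sign, logdet = np.linalg.slogdet(-hess)
    return 0.5 * float(logdet) if sign > 0 else 0.0


def estimate_common_precision(
    groups_by_event: Sequence[Sequence[np.ndarray]], max_events: int = 500
) -> float:
    """One precision shared across events, by summed Cox-Reid adjusted
    profile likelihood under the per-condition (full) design.

    The adjustment penalizes the proportion parameters estimated per event
    and condition, removing the small-sample upward bias a plain profile
    maximum would carry.  With many events the sum is evaluated on an
    evenly spaced subset of ``max_events`` (the estimator is already
    precise well below that).
    """
    if not groups_by_event:
        raise ValidationError("no events to estimate precision from")
    if len(groups_by_event) > max_events:
        idx = np.linspace(0, len(groups_by_event) - 1, max_events).astype(int)
        groups_by_event = [groups_by_event[i] for i in idx]

    def apl(phi: float) -> float:
        total = 0.0
        for groups in groups_by_event:
            for y in groups:
                pi = _fit_pi(y, phi)
                total += dm_loglik(y, pi, phi) - _cr_adjustment(y, pi, phi)
        return total

    return _maximize_over_phi(apl)


#: per-event expression filters; mouse preset (human: 8/4/10/0)
DM_FILTERS_MOUSE = dict(
    min_samps_gene_expr=6, min_samps_feature_expr=3, min_gene_expr=10, min_feature_expr=0
)
DM_FILTERS_HUMAN = dict(
    min_samps_gene_expr=8, min_samps_feature_expr=4, min_gene_expr=10, min_feature_expr=0
)


def dm_lrt(
    events: Sequence[ASEvent],
    counts,
    control: str = "control",
    treated: str = "LPS",
    min_samps_gene_expr: int = 6,
    min_samps_feature_expr: int = 3,
    min_gene_expr: int = 10,
    min_feature_expr: int = 0,
    precision: Optional[float] = None,
) -> pd.DataFrame:
    """Dirichlet-multinomial LRT per event, with expression filters.

    An event is tested when >= ``min_samps_gene_expr`` samples carry an
    event total >= ``min_gene_expr`` and every candidate reaches
    ``min_feature_expr`` in >= ``min_samps_feature_expr`` samples.  Unless
    ``precision`` is given, one common precision is estimated across all
    tested events (Cox-Reid adjusted profile likelihood).  The raw p-value
    is the upper chi-square tail of the LRT statistic; BH runs across
    tested events; delta PSI is the difference of mean observed per-sample
    proportions, in percent.
    """
    ctrl = counts.samples_of(control)
    trt = counts.samples_of(treated)
    tested: list[tuple] = []
    excluded: dict[str, str] = {}
    for ev in events:
        rids = [ev.row_id(i) for i in range(len(ev.candidates))]
        y = counts.counts.loc[rids]
        yc = y[ctrl].to_numpy(dtype=float).T  # samples x candidates
        yt = y[trt].to_numpy(dtype=float).T
        ally = np.vstack([yc, yt])
        tot = ally.sum(axis=1)
        if (tot >= min_gene_expr).sum() < min_samps_gene_expr:
            excluded[ev.event_id] = "min_samps_gene_expr"
            continue
        feat_ok = (ally >= min_feature_expr).sum(axis=0) >= min_samps_feature_expr
        if not feat_ok.all():
            excluded[ev.event_id] = "min_samps_feature_expr"
            continue
        if yc.sum() == 0 or yt.sum() == 0:
            excluded[ev.event_id] = "all-zero condition"
            continue
        tested.append((ev, yc, yt))

    phi = precision
    if phi is None and tested:
        phi = estimate_common_precision([(yc, yt) for _, yc, yt in tested])

    rows = []
    event_p: dict[str, float] = {}
    for ev, yc, yt in tested:
        fit = dm_fit({control: yc, treated: yt}, phi=phi)
        p = float(stats.chi2.sf(fit.lrt_stat, fit.df)) if fit.df > 0 else np.nan
        event_p[ev.event_id] = p

        def _mean_props(mat: np.ndarray) -> np.ndarray:
            tots = mat.sum(axis=1)
            ok = tots > 0
            if not ok.any():
                return np.full(mat.shape[1], np.nan)
            return (mat[ok] / tots[ok, None]).mean(axis=0)

        pc = _mean_props(yc) * 100.0
        pt = _mean_props(yt) * 100.0
        for idx, cand in enumerate(ev.candidates):
            rows.append(
                {
                    "event_id": ev.event_id,
                    "candidate": cand.label,
                    "candidate_index": idx,
                    "event_type": ev.event_type,
                    "novelty": ev.novelty,
                    "gene_id": ev.gene_id,
                    "mean_psi_control": pc[idx],
                    "mean_psi_treated": pt[idx],
                    "delta_psi": pt[idx] - pc[idx],
                    "p_raw": p,
                    "test": "dmlrt",
                }
            )
    out = pd.DataFrame(rows, columns=[c for c in RESULT_COLUMNS if c not in ("p_adj", "significant")])
    if len(out):
        adj = pd.Series(
            bh_adjust(pd.Series(event_p)), index=pd.Index(event_p.keys())
        )
        out["p_adj"] = out["event_id"].map(adj)
    else:
        out["p_adj"] = pd.Series(dtype=float)
    out["significant"] = False
    if excluded:
        log.info("dm_lrt excluded %d events by filters", len(excluded))
    out.attrs["excluded"] = excluded
    out.attrs["precision"] = phi
    return out[RESULT_COLUMNS]


# ---------------------------------------------------------------------------
# significance, union, ranking, conservation


def significant_events(
    results: pd.DataFrame, alpha: float = 0.25, delta: float = 10.0
) -> pd.DataFrame:
    """Keep rows with p_adj <= alpha and |delta PSI| >= delta.

    Novel intron-retention rows (type IR, novelty N) are removed regardless
    of significance.  A strict preset uses alpha = 0.05.
    """
    keep = (
        (results["p_adj"] <= alpha)
        & (results["delta_psi"].abs() >= delta)
        & ~((results["event_type"] == "IR") & (results["novelty"] == "N"))
    )
    out = results.loc[keep.fillna(False)].copy()
    out["significant"] = True
    return out


def union_genes(
    res_ttest: pd.DataFrame, res_dm: pd.DataFrame
) -> dict[str, set[str]]:
    """Per event type, the deduplicated union of gene ids from both tests."""
    out: dict[str, set[str]] = {}
    for df in (res_ttest, res_dm):
        for etype, sub in df.groupby("event_type"):
            out.setdefault(etype, set()).update(sub["gene_id"])
    return out


def ranking_composition(
    results: pd.DataFrame,
    percents: Sequence[int] = (5, 10, 15, 20, 25),
    delta_min: float = 10.0,
) -> pd.DataFrame:
    """Event-type composition of the top k% events ordered by p-value.

    Rows are collapsed to one per event (smallest p, largest |delta PSI|),
    restricted to |delta PSI| >= ``delta_min``; per percent k, counts by
    event type among the top ceil(k% of N) events.  Ties break on event_id.
    """
    per_event = (
        results.dropna(subset=["p_raw"])
        .sort_values(["p_raw", "event_id"])
        .groupby("event_id", sort=False)
        .agg(
            p_raw=("p_raw", "min"),
            event_type=("event_type", "first"),
            max_abs_delta=("delta_psi", lambda s: s.abs().max()),
        )
        .reset_index()
    )
    per_event = per_event[per_event["max_abs_delta"] >= delta_min]
    per_event = per_event.sort_values(["p_raw", "event_id"]).reset_index(drop=True)
    n = len(per_event)
    rows = {}
    for k in percents:
        top = per_event.head(int(np.ceil(k / 100.0 * n)))
        rows[k] = top["event_type"].value_counts().to_dict()
    out = pd.DataFrame(rows).T.fillna(0).astype(int)
    out.index.name = "top_percent"
    return out


def conserved_genes(
    gene_sets_by_species: Mapping[str, Mapping[str, Iterable[str]]],
    ortholog_map: Optional[Mapping[str, str]] = None,
) -> dict[str, set[str]]:
    """Per event type, genes significant in every species.

    Default ortholog mapping is case-insensitive symbol identity (mouse
    Aim2 <-> human AIM2); an explicit map overrides it.  Unmapped genes are
    non-conserved.
    """
    species = list(gene_sets_by_species)
    if len(species) < 2:
        raise ValidationError("need >= 2 species")

    def norm(g: str) -> str:
        if ortholog_map is not None:
            return ortholog_map.get(g, g)
        return g.upper()

    etypes = set()
    for sets in gene_sets_by_species.values():
        etypes.update(sets)
    out: dict[str, set[str]] = {}
    first = species[0]
    for et in sorted(etypes):
        base = set(gene_sets_by_species[first].get(et, ()))
        keys = [
            {norm(g) for g in gene_sets_by_species[sp].get(et, ())}
            for sp in species[1:]
        ]
        out[et] = {g for g in base if all(norm(g) in k for k in keys)}
    return out
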