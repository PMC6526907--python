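"""Assignment of genome scaffolds to X chromosomes vs autosomes.

Input is a table of per-scaffold read counts from two flow-sorted sperm-nucleus
pools: pool "0" (nuclei without the X chromosomes) and pool "X1X2" (nuclei
carrying both X chromosomes). For each scaffold the statistic

    P0 = reads_pool0 / (reads_pool0 + reads_poolX)

is near 0 for X-linked scaffolds (pool 0 carries no X chromatin apart from
sorting impurity) and near 0.5 for autosomal scaffolds. A two-component beta
mixture fitted by EM separates the two modes, and posterior membership
probabilities drive FDR-controlled P0 thresholds for calling scaffolds X,
autosomal, or unassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

POOL_COLUMNS = ["scaffold_id", "length", "reads_pool0", "reads_poolX"]


def _validate_pool_counts(counts: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in POOL_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"pool-count table missing columns {missing}")
    if counts["scaffold_id"].duplicated().any():
        raise ValueError("scaffold_id values must be unique")
    if (counts[["reads_pool0", "reads_poolX"]] < 0).any().any():
        raise ValueError("read counts must be nonnegative")
    return counts


def normalize_pools(counts: pd.DataFrame, seed: int | None = None) -> pd.DataFrame:
    """Equalize pool totals by hypergeometric down-sampling of the larger pool.

    Reads of the larger pool are subsampled without replacement across
    scaffolds (multivariate hypergeometric), so each scaffold's expected count
    after subsampling is its original count times target/total. The smaller
    pool is returned unchanged.
    """
    counts = _validate_pool_counts(counts).copy()
    totals = {
        "reads_pool0": int(counts["reads_pool0"].sum()),
        "reads_poolX": int(counts["reads_poolX"].sum()),
    }
    if min(totals.values()) == 0:
        raise ValueError("a pool with zero total reads cannot be normalized")
    if totals["reads_pool0"] == totals["reads_poolX"]:
        return counts
    larger = max(totals, key=totals.get)
    target = min(totals.values())
    rng = np.random.default_rng(seed)
    sub = rng.multivariate_hypergeometric(
        counts[larger].to_numpy(dtype=np.int64), target, method="marginals"
    )
    counts[larger] = sub
    return counts


def compute_p0(counts: pd.DataFrame, min_poolx: int = 100) -> pd.DataFrame:
    """P0 per scaffold with the candidate filter.

    Scaffolds with fewer than ``min_poolx`` reads in the X1X2 pool are kept in
    the table but flagged non-candidate (they stay unassigned downstream);
    scaffolds with zero reads in both pools are dropped with a warning.
    """
    counts = _validate_pool_counts(counts)
    total = counts["reads_pool0"] + counts["reads_poolX"]
    empty = total == 0
    if empty.any():
        logger.warning("dropping %d scaffolds with zero reads in both pools", empty.sum())
        counts = counts.loc[~empty]
        total = total.loc[~empty]
    out = pd.DataFrame(
        {
            "scaffold_id": counts["scaffold_id"],
            "p0": counts["reads_pool0"] / total,
            "total_reads": total.astype(np.int64),
            "candidate": counts["reads_poolX"] >= min_poolx,
        }
    ).reset_index(drop=True)
    return out


class BetaMixtureEM(BaseEstimator):
    """Two-component beta mixture fitted by EM with random restarts.

    Scikit-learn style estimator over values in (0, 1). Component 0 is the
    one with the smaller fitted mean (the X-linked mode for P0 data). The
    M-step uses weighted method-of-moments updates for the beta shapes, which
    is robust at the near-boundary X component.

    Attributes (after fit): ``means_``, ``shapes_`` (2x2 array of (a, b)),
    ``weights_``, ``loglik_``, ``converged_``, ``n_iter_``.
    """

    def __init__(
        self,
        n_init: int = 8,
        max_iter: int = 500,
        tol: float = 1e-8,
        eps: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.eps = eps
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.eps, 1.0 - self.eps)

    @staticmethod
    def _moment_shapes(x, w):
        wsum = w.sum()
        if wsum <= 0:
            return None
        m = float(np.sum(w * x) / wsum)
        v = float(np.sum(w * (x - m) ** 2) / wsum)
        v = max(v, 1e-12)
        c = m * (1.0 - m) / v - 1.0
        if c <= 0:
            c = 1e-3
        return max(m * c, 1e-3), max((1.0 - m) * c, 1e-3)

    def _em_once(self, x, sample_weight, a, b, w0):
        shapes = np.array([a, b], dtype=float)
        weights = np.array([w0, 1.0 - w0])
        loglik = -np.inf
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            logd = np.stack(
                [
                    np.log(weights[k])
                    + beta_dist.logpdf(x, shapes[k, 0], shapes[k, 1])
                    for k in range(2)
                ]
            )
            mx = logd.max(axis=0)
            lse = mx + np.log(np.exp(logd - mx).sum(axis=0))
            new_loglik = float(np.sum(sample_weight * lse))
            resp = np.exp(logd - lse)
            wresp = resp * sample_weight
            weights = wresp.sum(axis=1) / sample_weight.sum()
            if np.any(weights <= 0) or np.any(weights >= 1):
                return None
            for k in range(2):
                sh = self._moment_shapes(x, wresp[k])
                if sh is None:
                    return None
                shapes[k] = sh
            if np.isfinite(loglik) and abs(new_loglik - loglik) <= self.tol * (
                abs(new_loglik) + 1.0
            ):
                loglik = new_loglik
                converged = True
                break
            loglik = new_loglik
        return shapes, weights, loglik, converged, n_iter

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y=None, sample_weight=None):
        x = self._clip(np.asarray(X, dtype=float).reshape(-1))
        if x.size < 4:
            raise ValueError("need at least 4 observations to fit a 2-component mixture")
        sw = (
            np.ones_like(x)
            if sample_weight is None
            else np.asarray(sample_weight, dtype=float).reshape(-1)
        )
        if np.ptp(x) < 1e-9:
            # all values identical: mixture is unidentifiable
            self.means_ = np.array([float(x[0])] * 2)
            self.shapes_ = np.array([[1.0, 1.0], [1.0, 1.0]])
            self.weights_ = np.array([0.5, 0.5])
            self.loglik_ = float("nan")
            self.converged_ = False
            self.n_iter_ = 0
            return self
        rng = np.random.default_rng(self.random_state)
        best = None
        for trial in range(self.n_init):
            if trial == 0:
                split = float(np.quantile(x, 0.25))
            else:
                split = float(np.quantile(x, rng.uniform(0.05, 0.95)))
            lo = x <= split
            if lo.sum() < 2 or (~lo).sum() < 2:
                lo = x <= np.median(x)
            init = []
            ok = True
            for mask in (lo, ~lo):
                sh = self._moment_shapes(x[mask], sw[mask])
                if sh is None:
                    ok = False
                    break
                init.append(sh)
            if not ok:
                continue
            res = self._em_once(x, sw, init[0], init[1], max(lo.mean(), 0.05))
            if res is None:
                continue
            if best is None or res[2] > best[2]:
                best = res
        if best is None:
            raise RuntimeError("EM failed to produce a valid fit in any restart")
        shapes, weights, loglik, converged, n_iter = best
        means = shapes[:, 0] / shapes.sum(axis=1)
        order = np.argsort(means)
        self.shapes_ = shapes[order]
        self.weights_ = weights[order]
        self.means_ = means[order]
        self.loglik_ = loglik
        self.converged_ = bool(converged)
        self.n_iter_ = n_iter
        return self

    def predict_proba(self, X):
        x = self._clip(np.asarray(X, dtype=float).reshape(-1))
        logd = np.stack(
            [
                np.log(self.weights_[k])
                + beta_dist.logpdf(x, self.shapes_[k, 0], self.shapes_[k, 1])
                for k in range(2)
            ],
            axis=1,
        )
        mx = logd.max(axis=1, keepdims=True)
        p = np.exp(logd - mx)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.predict_proba(X).argmax(axis=1)


@dataclass
class MixtureFit:
    """Result of the P0 mixture fit on candidate scaffolds."""

    mean_x: float
    mean_a: float
    spread_x: tuple[float, float]
    spread_a: tuple[float, float]
    weight_x: float
    posterior_x: pd.Series  # indexed by scaffold_id, candidates only
    loglik: float
    converged: bool
    model: BetaMixtureEM = field(repr=False, default=None)


def fit_p0_mixture(
    records: pd.DataFrame, seed: int | None = None, weighted: bool = False
) -> MixtureFit:
    """Fit the two-component beta mixture to candidate P0 values.

    ``weighted=True`` weights each scaffold by its total read count in the
    likelihood (per-read density); the default is one point per scaffold.
    """
    cand = records.loc[records["candidate"]]
    if len(cand) < 50:
        raise ValueError(
            f"only {len(cand)} candidate scaffolds; need >= 50 for a stable mixture fit"
        )
    est = BetaMixtureEM(random_state=seed)
    sw = cand["total_reads"].to_numpy(dtype=float) if weighted else None
    est.fit(cand["p0"].to_numpy(), sample_weight=sw)
    if est.converged_:
        post = est.predict_proba(cand["p0"].to_numpy())[:, 0]
    else:
        post = np.full(len(cand), np.nan)
    return MixtureFit(
        mean_x=float(est.means_[0]),
        mean_a=float(est.means_[1]),
        spread_x=tuple(est.shapes_[0]),
        spread_a=tuple(est.shapes_[1]),
        weight_x=float(est.weights_[0]),
        posterior_x=pd.Series(post, index=cand["scaffold_id"].to_numpy()),
        loglik=est.loglik_,
        converged=est.converged_,
        model=est,
    )


def assign_scaffolds(
    fit: MixtureFit,
    records: pd.DataFrame,
    fdr: float = 0.025,
    force: bool = False,
) -> pd.DataFrame:
    """FDR-thresholded X/autosome/unassigned labels.

    The X threshold t_x is the largest P0 cutoff such that the expected
    proportion of autosomal scaffolds (1 - posterior) among calls below it is
    at most ``fdr``; t_a symmetrically bounds expected X contamination among
    autosomal calls. Scaffolds between the thresholds, and non-candidates,
    stay unassigned.
    """
    if not 0.0 < fdr < 0.5:
        raise ValueError("fdr must lie in (0, 0.5)")
    if not fit.converged and not force:
        raise RuntimeError("mixture fit did not converge; pass force=True to override")
    cand = records.loc[records["candidate"]].copy()
    cand["posterior_x"] = fit.posterior_x.reindex(cand["scaffold_id"]).to_numpy()
    cand = cand.sort_values("p0", kind="mergesort").reset_index(drop=True)
    p0 = cand["p0"].to_numpy()
    post = cand["posterior_x"].to_numpy()

    t_x = _prefix_threshold(p0, 1.0 - post, fdr, from_low=True)
    t_a = _prefix_threshold(p0, post, fdr, from_low=False)
    if t_x > t_a:  # overlapping calls are resolved conservatively
        t_x = t_a = 0.5 * (t_x + t_a)

    labels = np.where(p0 < t_x, "X", np.where(p0 > t_a, "AUTOSOME", "UNASSIGNED"))
    cand["label"] = labels
    non = records.loc[~records["candidate"]].copy()
    non["posterior_x"] = np.nan
    non["label"] = "UNASSIGNED"
    out = pd.concat([cand, non], ignore_index=True)
    out["t_x"] = t_x
    out["t_a"] = t_a
    out["nominal_fdr"] = fdr
    return out[
        ["scaffold_id", "label", "p0", "posterior_x", "t_x", "t_a", "nominal_fdr"]
    ]


def _prefix_threshold(p0, error_prob, fdr, from_low: bool) -> float:
    """Largest (from_low) or smallest cutoff with running mean error <= fdr."""
    n = len(p0)
    if from_low:
        run = np.cumsum(error_prob) / np.arange(1, n + 1)
        ok = np.nonzero(run <= fdr)[0]
        if ok.size == 0:
            return 0.0
        k = ok[-1]
        return float(0.5 * (p0[k] + p0[k + 1])) if k + 1 < n else float(p0[k] + 1e-9)
    run = np.cumsum(error_prob[::-1]) / np.arange(1, n + 1)
    ok = np.nonzero(run <= fdr)[0]
    if ok.size == 0:
        return 1.0
    k = n - 1 - ok[-1]
    return float(0.5 * (p0[k] + p0[k - 1])) if k > 0 else float(p0[k] - 1e-9)


def assignment_to_bed(table: pd.DataFrame, lengths: pd.DataFrame) -> pd.DataFrame:
    """Whole-scaffold BED intervals (0-based half-open) named by label."""
    merged = table.merge(lengths[["scaffold_id", "length"]], on="scaffold_id")
    return pd.DataFrame(
        {
            "chrom": merged["scaffold_id"],
            "start": 0,
            "end": merged["length"].astype(int),
            "name": merged["label"],
        }
    )
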