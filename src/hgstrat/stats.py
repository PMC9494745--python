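"""Inference layer: Spearman correlations and PLS models with LOO q2.

Links the molecular predictors (gyrB-normalized hgcA/hgcB gene and transcript
abundances) and the chemical predictor (concentration of dissolved
Hg(II)-sulfide species) to the three Hg response parameters: the methylation
rate constant k_meth, the MeHg concentration, and the MeHg/HgT molar ratio.

Spearman rank correlation (average ranks on ties, two-tailed t-approximation)
is reported as rho and rho^2.  Joint models are one-component partial
least-squares (PLS, NIPALS) regressions on mean-centered, unit-variance
predictors; goodness of fit is r2 = 1 - RSS/TSS and predictive ability is the
leave-one-out cross-validated q2 = 1 - PRESS/TSS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cross_decomposition import PLSRegression

from .kinetics import TYPICAL_DL_K_METH

__all__ = [
    "CorrelationResult",
    "PLSModel",
    "spearman",
    "fit_pls",
    "loo_q2",
    "joint_model_report",
]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    rho_sq: float
    p_value: float
    n: int
    defined: bool = True


@dataclass
class PLSModel:
    n_components: int
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    r_sq: float
    q_sq: float | None
    n: int
    fitted: np.ndarray = field(repr=False, default=None)


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with a two-tailed significance test.

    Average ranks on ties; p from the t-approximation (requires n > 3).
    A constant vector makes the correlation undefined: flagged, not raised.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("missing values: caller must filter")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(np.nan, np.nan, np.nan, n, defined=False)
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(float(rho), float(rho) ** 2, float(p), n)


def _validate_xy(X, y, min_n: int = 5) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y row counts differ")
    if X.shape[0] < min_n:
        raise ValueError(f"need n >= {min_n}")
    sd = X.std(axis=0)
    dead = np.nonzero(sd == 0)[0]
    if dead.size:
        raise ValueError(f"zero-variance predictor column(s): {dead.tolist()}")
    if y.std() == 0:
        raise ValueError("constant response")
    return X, y


def fit_pls(X, y, n_components: int = 1) -> PLSModel:
    """One-or-more-component PLS regression (NIPALS) with internal scaling.

    Columns of X and y are mean-centered and scaled to unit variance before
    extraction; r2 is computed on the fitted response in original units.
    """
    X, y = _validate_xy(X, y)
    pls = PLSRegression(n_components=n_components, scale=True)
    with warnings.catch_warnings():
        # with a single response the y-residual is exhausted after the first
        # component; sklearn warns, which is expected here
        warnings.filterwarnings("ignore", message="y residual is constant")
        pls.fit(X, y)
    yhat = pls.predict(X).ravel()
    rss = float(np.sum((y - yhat) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return PLSModel(
        n_components=n_components,
        x_weights=pls.x_weights_.copy(),
        x_loadings=pls.x_loadings_.copy(),
        y_loadings=pls.y_loadings_.copy(),
        r_sq=1.0 - rss / tss,
        q_sq=None,
        n=y.size,
        fitted=yhat,
    )


def loo_q2(X, y, n_components: int = 1) -> float:
    """Leave-one-out cross-validated q2 = 1 - PRESS/TSS for a PLS model.

    Each left-out sample is predicted from a PLS refit on the remaining
    n - 1 rows; TSS is about the full-sample mean.  May be negative for a
    model with no predictive ability.
    """
    X, y = _validate_xy(X, y)
    n = y.size
    press = 0.0
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="y residual is constant")
        for i in range(n):
            mask = np.ones(n, bool)
            mask[i] = False
            pls = PLSRegression(n_components=n_components, scale=True)
            pls.fit(X[mask], y[mask])
            pred = float(pls.predict(X[i][None, :]).ravel()[0])
            press += (y[i] - pred) ** 2
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / tss


# ---------------------------------------------------------------------------
# the joint report
# ---------------------------------------------------------------------------

_ABUNDANCE_COLS = ("hgca_gene", "hgca_transcript", "hgcb_gene", "hgcb_transcript")
_HG_PARAMS = ("k_meth", "mehg", "mehg_hgt_ratio")


def joint_model_report(
    samples: pd.DataFrame,
    nondetect_substitute: float = TYPICAL_DL_K_METH / 2,
    use_speciation: bool = True,
) -> dict:
    """Run the full correlation/PLS battery over a joined per-sample table.

    ``samples`` needs columns sample_id, depth, zone, k_meth (NaN marks a
    non-detect), k_meth_detectable (optional), mehg, mehg_hgt_ratio, the four
    hgc abundance columns and diss_sulfide_conc.  Non-detect k_meth values
    are substituted at half the typical detection limit for rank statistics
    and PLS fits (ranks are insensitive to the exact value as long as it is
    below all detects).

    Returns a dict with ``spearman`` (one entry per abundance x Hg-parameter
    pair), ``pls`` (each Hg parameter on [hgcA abundance, dissolved-sulfide
    concentration] — or abundance alone when ``use_speciation`` is False),
    and the n used.
    """
    df = samples.copy()
    required = ["k_meth", "mehg", "mehg_hgt_ratio", *_ABUNDANCE_COLS]
    if use_speciation:
        required.append("diss_sulfide_conc")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"joined table missing columns: {missing}")
    df["k_meth"] = df["k_meth"].fillna(nondetect_substitute)
    df = df.dropna(subset=[c for c in required if c != "k_meth"])
    if len(df) < 5:
        raise ValueError(f"need >= 5 complete rows, have {len(df)}")

    report: dict = {"n": int(len(df)), "speciation_used": bool(use_speciation),
                    "spearman": {}, "pls": {}}
    for ab in _ABUNDANCE_COLS:
        for hg in _HG_PARAMS:
            res = spearman(df[ab].to_numpy(), df[hg].to_numpy())
            report["spearman"][f"{ab}~{hg}"] = {
                "rho": res.rho, "rho_sq": res.rho_sq,
                "p_value": res.p_value, "n": res.n, "defined": res.defined,
            }

    for ab in ("hgca_gene", "hgca_transcript"):
        for hg in _HG_PARAMS:
            cols = [ab, "diss_sulfide_conc"] if use_speciation else [ab]
            X = df[cols].to_numpy()
            y = df[hg].to_numpy()
            try:
                model = fit_pls(X, y, n_components=1)
                q2 = loo_q2(X, y, n_components=1)
            except ValueError as exc:
                report["pls"][f"{hg}~{'+'.join(cols)}"] = {"error": str(exc)}
                continue
            report["pls"][f"{hg}~{'+'.join(cols)}"] = {
                "r_sq": model.r_sq, "q_sq": q2, "n": model.n,
                "predictors": cols,
            }
    return report
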