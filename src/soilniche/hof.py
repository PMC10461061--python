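"""Huisman-Olff-Fresco (HOF) species response curves I-VII.

The HOF hierarchy describes a taxon's response y(x) along an
environmental gradient x in [0, 1], from flat (I) through monotone
sigmoid (II, III), symmetric (IV) and skewed (V) unimodal, to bimodal
(VI, VII).  Writing s(t) = 1/(1 + e^t):

    I    M s(a)
    II   M s(a + b x)
    III  M s(a + b x) s(c)
    IV   M s(a + b x) s(c - b x)
    V    M s(a + b x) s(c + d x)
    VI   type IV plus a second type-IV peak shifted by d2 with height
         fraction h (same width b)
    VII  as VI but the second peak has its own width b2

Each type is fitted by Gaussian nonlinear least squares on max-scaled
abundances with random restarts; the winning type is the AICc minimum,
cross-checked by re-selection on a small number of bootstrap resamples.
Niche optima and edges follow machine rules: the optimum is the interior
argmax of the fitted curve (none for flat or monotone types, none when
bimodal optima sit at the gradient edges), and niche edges are the
inflection points flanking the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit
from sklearn.base import BaseEstimator

__all__ = [
    "HOF_TYPES",
    "PARAM_NAMES",
    "HofFit",
    "NicheRecord",
    "NicheResponseCurve",
    "OccurrenceBelowThreshold",
    "hof_curve",
    "fit_hof_all",
    "select_model",
    "niche_metrics",
]

HOF_TYPES = ("I", "II", "III", "IV", "V", "VI", "VII")

PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "I": ("M", "a"),
    "II": ("M", "a", "b"),
    "III": ("M", "a", "b", "c"),
    "IV": ("M", "a", "b", "c"),
    "V": ("M", "a", "b", "c", "d"),
    "VI": ("M", "a", "b", "c", "d2", "h"),
    "VII": ("M", "a", "b", "c", "d2", "h", "b2"),
}

_BOUNDS = {
    "M": (1e-3, 5.0),
    "a": (-50.0, 50.0),
    "b": (-200.0, 200.0),
    "c": (-50.0, 50.0),
    "d": (-200.0, 200.0),
    "d2": (0.02, 0.98),
    "h": (1e-3, 1.0),
    "b2": (-200.0, 200.0),
}


class OccurrenceBelowThreshold(ValueError):
    """Raised when a taxon has too few positive observations to model."""


#: A bimodal fit (VI/VII) only counts as bimodal when its lesser peak
#: rises above the saddle between the peaks by at least this fraction of
#: the fitted response range; otherwise the "second peak" is a noise
#: spike and the type is ineligible during model selection.  This is the
#: machine equivalent of visually rejecting spurious bimodal fits.
SECOND_PEAK_PROMINENCE = 0.1


def _interior_maxima(yy: np.ndarray) -> list[int]:
    """Indices of interior local maxima, ignoring float-level wiggles in
    saturated (flat) curve regions."""
    n = yy.size
    eps = 1e-9 * max(float(np.ptp(yy)), 1e-30)
    return [
        i
        for i in range(1, n - 1)
        if yy[i] > yy[i - 1] + eps and yy[i] >= yy[i + 1] - eps
    ]


def _is_bimodal(model_type: str, params: Mapping[str, float], n_grid: int = 501) -> bool:
    grid = np.linspace(0.0, 1.0, n_grid)
    yy = hof_curve(model_type, params, grid)
    maxima = _interior_maxima(yy)
    if len(maxima) < 2:
        return False
    top = sorted(maxima, key=lambda i: yy[i], reverse=True)[:2]
    i1, i2 = sorted(top)
    trough = yy[i1 : i2 + 1].min()
    span = yy.max() - yy.min()
    if span <= 0:
        return False
    prominence = min(yy[i1], yy[i2]) - trough
    return prominence >= SECOND_PEAK_PROMINENCE * span


def _s(t: np.ndarray) -> np.ndarray:
    # 1 / (1 + e^t), overflow-safe
    return expit(-t)


def _as_array(model_type: str, params: Mapping[str, float] | Sequence[float]) -> np.ndarray:
    names = PARAM_NAMES[model_type]
    if isinstance(params, Mapping):
        missing = [k for k in names if k not in params]
        if missing:
            raise ValueError(f"type {model_type} missing parameters {missing}")
        vec = np.array([float(params[k]) for k in names])
    else:
        vec = np.asarray(params, dtype=float)
        if vec.size != len(names):
            raise ValueError(
                f"type {model_type} expects {len(names)} parameters "
                f"({', '.join(names)}), got {vec.size}"
            )
    if vec[0] <= 0:
        raise ValueError("scale parameter M must be positive")
    return vec


def hof_curve(
    model_type: str,
    params: Mapping[str, float] | Sequence[float],
    x: np.ndarray,
) -> np.ndarray:
    """Evaluate a HOF response curve at gradient positions ``x``."""
    if model_type not in HOF_TYPES:
        raise ValueError(f"unknown HOF type {model_type!r}")
    v = _as_array(model_type, params)
    x = np.asarray(x, dtype=float)
    if model_type == "I":
        M, a = v
        return np.full_like(x, M * float(_s(np.array(a))))
    if model_type == "II":
        M, a, b = v
        return M * _s(a + b * x)
    if model_type == "III":
        M, a, b, c = v
        return M * _s(a + b * x) * float(_s(np.array(c)))
    if model_type == "IV":
        M, a, b, c = v
        return M * _s(a + b * x) * _s(c - b * x)
    if model_type == "V":
        M, a, b, c, d = v
        return M * _s(a + b * x) * _s(c + d * x)
    if model_type == "VI":
        M, a, b, c, d2, h = v
        main = M * _s(a + b * x) * _s(c - b * x)
        xx = x - d2
        return main + h * M * _s(a + b * xx) * _s(c - b * xx)
    M, a, b, c, d2, h, b2 = v
    main = M * _s(a + b * x) * _s(c - b * x)
    xx = x - d2
    return main + h * M * _s(a + b2 * xx) * _s(c - b2 * xx)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _aicc(rss: float, n: int, n_params: int) -> float:
    k = n_params + 1  # + residual variance
    if n - k - 1 <= 0:
        return np.inf
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _heuristic_starts(model_type: str, x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    ybar = float(np.clip(y.mean(), 1e-3, 1 - 1e-3))
    ymax = float(max(y.max(), 1e-3))
    xm = float(x[np.argmax(y)])
    slope = float(np.corrcoef(x, y)[0, 1]) if np.std(y) > 0 else 0.0
    starts: list[list[float]] = []
    if model_type == "I":
        starts.append([1.0, np.log(1.0 / ybar - 1.0)])
    elif model_type in ("II", "III"):
        b0 = -10.0 if slope >= 0 else 10.0
        base = [1.0, -b0 * 0.5, b0]
        starts.append(base + ([0.0] if model_type == "III" else []))
        starts.append([1.0, b0 * 0.5, -b0] + ([0.0] if model_type == "III" else []))
    else:
        # peak-shaped heuristics: place (c - a)/(2b) at the empirical argmax
        for b0 in (10.0, 30.0):
            a0, c0 = -2.0 - b0 * xm, -2.0 + b0 * xm
            M0 = min(ymax / (float(_s(np.array(-2.0))) ** 2), _BOUNDS["M"][1])
            core = [M0, a0, b0, c0]
            if model_type == "IV":
                starts.append(core)
            elif model_type == "V":
                starts.append(core + [-b0])
            elif model_type == "VI":
                starts.append(core + [0.3, 0.5])
                starts.append(core + [0.6, 0.5])
            else:
                starts.append(core + [0.3, 0.5, b0])
                starts.append(core + [0.6, 0.5, b0])
    return [np.array(s, dtype=float) for s in starts]


def _random_start(model_type: str, rng: np.random.Generator) -> np.ndarray:
    draw = {
        "M": rng.uniform(0.2, 2.0),
        "a": rng.uniform(-10, 10),
        "b": rng.uniform(-40, 40),
        "c": rng.uniform(-10, 10),
        "d": rng.uniform(-40, 40),
        "d2": rng.uniform(0.05, 0.95),
        "h": rng.uniform(0.05, 1.0),
        "b2": rng.uniform(-40, 40),
    }
    return np.array([draw[name] for name in PARAM_NAMES[model_type]])


def _fit_type(
    model_type: str,
    x: np.ndarray,
    y: np.ndarray,
    starts: Sequence[np.ndarray],
) -> dict:
    names = PARAM_NAMES[model_type]
    lo = np.array([_BOUNDS[k][0] for k in names])
    hi = np.array([_BOUNDS[k][1] for k in names])

    def resid(v: np.ndarray) -> np.ndarray:
        return hof_curve(model_type, v, x) - y

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf", max_nfev=400)
        except Exception:  # noqa: BLE001 - a failed start is recorded, not fatal
            continue
        rss = float(2 * sol.cost)
        if best is None or rss < best["rss"]:
            best = {
                "params": dict(zip(names, sol.x)),
                "vector": sol.x,
                "rss": rss,
                "success": True,
            }
    if best is None:
        return {"params": None, "vector": None, "rss": np.inf, "success": False}
    n = len(x)
    best["aicc"] = _aicc(best["rss"], n, len(names))
    best["loglik"] = -0.5 * n * (np.log(2 * np.pi * max(best["rss"], 1e-300) / n) + 1)
    return best


def fit_hof_all(
    x: np.ndarray,
    y: np.ndarray,
    min_occ: int = 10,
    seed: int = 0,
    n_restarts: int = 5,
    types: Sequence[str] = HOF_TYPES,
) -> dict[str, dict]:
    """Fit every requested HOF type to one gradient.

    ``x`` is internally rescaled to [0, 1] and ``y`` to a maximum of 1;
    taxa with fewer than ``min_occ`` positive observations raise
    :class:`OccurrenceBelowThreshold`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n_occ = int((y > 0).sum())
    if n_occ < min_occ:
        raise OccurrenceBelowThreshold(
            f"minimum occurrence not met: {n_occ} positive observations < {min_occ}"
        )
    span = x.max() - x.min()
    xs = (x - x.min()) / span if span > 0 else np.zeros_like(x)
    ymax = y.max()
    if ymax <= 0:
        raise ValueError("all abundances are zero")
    ys = y / ymax
    rng = np.random.default_rng(seed)
    fits: dict[str, dict] = {}
    for t in types:
        starts = _heuristic_starts(t, xs, ys)
        starts += [_random_start(t, rng) for _ in range(n_restarts)]
        fit = _fit_type(t, xs, ys, starts)
        fit["n_occurrences"] = n_occ
        if fit["success"] and t in ("VI", "VII"):
            fit["eligible"] = _is_bimodal(t, fit["params"])
        else:
            fit["eligible"] = bool(fit["success"])
        fits[t] = fit
    return fits


_COMPLEXITY = {t: i for i, t in enumerate(HOF_TYPES)}

#: Models within this many AICc units of the minimum are treated as
#: equally supported and the least complex one wins (parsimony rule for
#: nested candidates).
AICC_MARGIN = 2.0


def _aicc_choice(scores: Mapping[str, float], margin: float = AICC_MARGIN) -> str:
    if not scores:
        raise ValueError("all HOF fits failed")
    best = min(scores.values())
    eligible = [t for t, s in scores.items() if s <= best + margin]
    return min(eligible, key=lambda t: _COMPLEXITY[t])


def select_model(
    fits: Mapping[str, dict],
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 5,
    seed: int = 0,
) -> tuple[str, list[str]]:
    """AICc-minimal type, stabilised by re-selection on ``n_boot``
    bootstrap resamples (warm-started from the full-data parameters).
    When the AICc choice is not the modal bootstrap choice, the modal
    choice wins; ties break toward the lower-complexity type."""
    ok = {
        t: f for t, f in fits.items()
        if f.get("success") and f.get("eligible", True)
    }
    choice = _aicc_choice({t: f["aicc"] for t, f in ok.items()})
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    span = x.max() - x.min()
    xs = (x - x.min()) / span if span > 0 else np.zeros_like(x)
    ys = y / y.max()
    rng = np.random.default_rng(seed)
    n = len(xs)
    boot_types: list[str] = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = xs[idx], ys[idx]
        scores: dict[str, float] = {}
        for t, f in ok.items():
            refit = _fit_type(t, xb, yb, [f["vector"]])
            if not refit["success"]:
                continue
            if t in ("VI", "VII") and not _is_bimodal(t, refit["params"]):
                continue
            scores[t] = refit["aicc"]
        if scores:
            boot_types.append(_aicc_choice(scores))
    if boot_types:
        counts: dict[str, int] = {}
        for t in boot_types:
            counts[t] = counts.get(t, 0) + 1
        modal = min(counts, key=lambda t: (-counts[t], _COMPLEXITY[t]))
        if modal != choice:
            choice = modal
    return choice, boot_types


# ---------------------------------------------------------------------------
# niche metrics
# ---------------------------------------------------------------------------

@dataclass
class NicheRecord:
    optimum: float | None
    low_edge: float | None
    high_edge: float | None
    optima: list[float] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


def niche_metrics(
    model_type: str,
    params: Mapping[str, float],
    x_range: tuple[float, float] = (0.0, 1.0),
    edge_tolerance: float = 0.05,
    n_grid: int = 2001,
) -> NicheRecord:
    """Optimum and inflection-point niche edges from a fitted curve.

    Flat (I) and monotone (II, III) types carry no optimum; bimodal
    types whose interior maxima all sit within ``edge_tolerance`` of the
    range ends are interpreted as having no optimum.  When no interior
    inflection exists on a side, that edge falls back to the range end
    and is flagged.
    """
    lo, hi = x_range
    grid = np.linspace(0.0, 1.0, n_grid)
    yy = hof_curve(model_type, params, grid)

    def to_user(u: float) -> float:
        return lo + u * (hi - lo)

    maxima = _interior_maxima(yy)
    optima = [to_user(grid[i]) for i in maxima]

    if model_type == "I":
        return NicheRecord(None, None, None, [], ["flat"])
    if model_type in ("II", "III"):
        return NicheRecord(None, None, None, optima, ["monotone"])
    if not maxima:
        return NicheRecord(None, None, None, [], ["no_interior_maximum"])

    keep = maxima
    flags: list[str] = []
    if model_type in ("VI", "VII"):
        keep = [i for i in maxima if edge_tolerance <= grid[i] <= 1 - edge_tolerance]
        if not keep:
            return NicheRecord(None, None, None, optima, ["optima_at_range_edges"])
    i_opt = max(keep, key=lambda i: yy[i])
    u_opt = grid[i_opt]

    d1 = np.gradient(yy, grid)
    d2 = np.gradient(d1, grid)
    signs = np.sign(d2)
    flips = np.where(np.diff(signs) != 0)[0]
    below = [grid[i] for i in flips if grid[i] < u_opt]
    above = [grid[i + 1] for i in flips if grid[i + 1] > u_opt]
    if below:
        low = to_user(max(below))
    else:
        low, flags = to_user(0.0), flags + ["low_edge_at_range_end"]
    if above:
        high = to_user(min(above))
    else:
        high, flags = to_user(1.0), flags + ["high_edge_at_range_end"]
    return NicheRecord(to_user(u_opt), low, high, optima, flags)


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

@dataclass
class HofFit:
    fits: dict[str, dict]
    chosen_type: str
    bootstrap_types: list[str]
    niche: NicheRecord
    n_occurrences: int
    x_range: tuple[float, float]
    y_scale: float


class NicheResponseCurve(BaseEstimator):
    """Fit the HOF family along one gradient and extract the niche.

    Parameters mirror the analysis defaults: minimum occurrence 10,
    bootstrap model re-selection with n_boot=5, AICc selection, 5 random
    restarts per type, 5% edge tolerance for the bimodal edge rule.
    """

    def __init__(
        self,
        min_occ: int = 10,
        n_boot: int = 5,
        n_restarts: int = 5,
        edge_tolerance: float = 0.05,
        n_grid: int = 2001,
        seed: int = 0,
        types: tuple[str, ...] = HOF_TYPES,
    ):
        self.min_occ = min_occ
        self.n_boot = n_boot
        self.n_restarts = n_restarts
        self.edge_tolerance = edge_tolerance
        self.n_grid = n_grid
        self.seed = seed
        self.types = types

    def fit(self, X, y) -> "NicheResponseCurve":
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        self.x_range_ = (float(x.min()), float(x.max()))
        self.y_scale_ = float(y.max())
        fits = fit_hof_all(
            x, y, min_occ=self.min_occ, seed=self.seed,
            n_restarts=self.n_restarts, types=self.types,
        )
        chosen, boot = select_model(fits, x, y, n_boot=self.n_boot, seed=self.seed)
        niche = niche_metrics(
            chosen, fits[chosen]["params"], x_range=self.x_range_,
            edge_tolerance=self.edge_tolerance, n_grid=self.n_grid,
        )
        self.fits_ = fits
        self.chosen_type_ = chosen
        self.params_ = fits[chosen]["params"]
        self.bootstrap_types_ = boot
        self.niche_ = niche
        self.n_occurrences_ = fits[chosen]["n_occurrences"]
        return self

    def predict(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).ravel()
        lo, hi = self.x_range_
        span = hi - lo
        xs = (x - lo) / span if span > 0 else np.zeros_like(x)
        return self.y_scale_ * hof_curve(self.chosen_type_, self.params_, xs)

    def result(self) -> HofFit:
        return HofFit(
            fits=self.fits_,
            chosen_type=self.chosen_type_,
            bootstrap_types=self.bootstrap_types_,
            niche=self.niche_,
            n_occurrences=self.n_occurrences_,
            x_range=self.x_range_,
            y_scale=self.y_scale_,
        )


def diagnostic_plot(model: NicheResponseCurve, x, y, ax=None):
    """Audit plot of data, fitted curve, optimum and edges (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xg = np.linspace(model.x_range_[0], model.x_range_[1], 400)
    ax.scatter(x, y, s=8, alpha=0.5, label="data")
    ax.plot(xg, model.predict(xg), color="C1",
            label=f"HOF {model.chosen_type_}")
    n = model.niche_
    if n.optimum is not None:
        ax.axvline(n.optimum, color="C2", ls="--", label="optimum")
        for edge in (n.low_edge, n.high_edge):
            if edge is not None:
                ax.axvline(edge, color="C3", ls=":")
    ax.legend()
    return ax
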