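"""Maximum-likelihood spatially explicit capture–recapture (SECR).

Detections of an individual are modelled as arising from a latent
activity centre: the probability (or expected count) of detection at a
camera declines with distance ``d`` from the centre following a
half-normal curve ``g0 * exp(-d^2 / (2 sigma^2))``.  Activity centres of
the (unknown number of) individuals form a homogeneous Poisson process
of intensity ``D`` over a discretised habitat mask; integrating the
detection model over the mask yields a full likelihood for the observed
capture histories from which density, the detection intercept and the
spatial scale are estimated jointly.

Model variants mirror the standard heterogeneity ladder for camera-trap
studies of social species:

``null``
    one detection class; 3 parameters (D, g0, sigma).
``sex`` / ``group``
    two known classes (female/male, or group-living/solitary) with
    class-specific density, intercept and scale; 6 parameters.
``sexhet`` / ``grouphet``
    the known classes plus a 2-class latent finite mixture on (g0,
    sigma) within each known class — a shared link-scale offset and a
    shared mixing proportion; 9 parameters.

Two encounter models are available: ``bernoulli`` (binary detection per
detector-occasion, fractional effort entering as an exponent) and
``poisson_count`` (Poisson counts, effort as a rate multiplier).  The
number of detected individuals is Poisson by default; a binomial
n-distribution (fixed super-population on the mask) is provided as a
variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.stats import chi2, norm
from shapely.geometry import Point
from shapely.prepared import prep

from .datamodel import M2_PER_KM2, CaptureHistory, ParameterError

__all__ = [
    "HabitatMask", "SECRModelSpec", "SECRFit", "build_mask", "suggest_buffer",
    "rpsv", "detection_prob", "neg_log_likelihood", "fit_secr",
    "compare_models", "region_abundance", "circular_r95", "precision",
]

#: sqrt of the 95% quantile of chi-square(2); multiplies sigma to give the
#: radius holding 95% of a circular bivariate-normal activity distribution.
R95_FACTOR = float(np.sqrt(chi2.ppf(0.95, 2)))

_Z95 = float(norm.ppf(0.975))


# ---------------------------------------------------------------------------
# habitat mask
# ---------------------------------------------------------------------------

@dataclass
class HabitatMask:
    """Discretised integration region for activity centres.

    ``points`` are habitat cell centres (metres); every cell has the same
    area ``cell_area_km2``.  Non-habitat cells are dropped at
    construction, so all stored cells contribute to sums.
    """

    points: np.ndarray          # (M, 2) habitat cell centres
    cell_area_km2: float
    spacing_m: float
    buffer_m: float

    @property
    def n_cells(self) -> int:
        return len(self.points)

    @property
    def area_km2(self) -> float:
        return self.n_cells * self.cell_area_km2


def build_mask(cameras_xy: np.ndarray, buffer_m: float, spacing_m: float | None = None,
               habitat=None) -> HabitatMask:
    """Lay a square lattice over the camera bounding box plus a buffer.

    ``habitat`` is an optional shapely geometry; cell centres falling
    outside it are flagged non-habitat and excluded.  Default spacing is
    ``buffer_m / 30`` (discretisation error well below reporting
    precision; coarser spacings are fine for exploratory fits).
    """
    if buffer_m <= 0:
        raise ParameterError("buffer_m must be positive")
    if spacing_m is None:
        spacing_m = buffer_m / 30.0
    if spacing_m <= 0:
        raise ParameterError("spacing_m must be positive")
    xy = np.asarray(cameras_xy, dtype=float).reshape(-1, 2)
    x0, y0 = xy.min(axis=0) - buffer_m
    x1, y1 = xy.max(axis=0) + buffer_m
    xs = np.arange(x0, x1 + spacing_m / 2, spacing_m)
    ys = np.arange(y0, y1 + spacing_m / 2, spacing_m)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    if habitat is not None:
        prepared = prep(habitat)
        inside = np.array([prepared.contains(Point(p)) for p in pts])
        pts = pts[inside]
    if len(pts) == 0:
        raise ParameterError("habitat mask has zero habitat cells")
    return HabitatMask(
        points=pts,
        cell_area_km2=spacing_m * spacing_m / M2_PER_KM2,
        spacing_m=float(spacing_m),
        buffer_m=float(buffer_m),
    )


def rpsv(history: CaptureHistory) -> float:
    """Root pooled spatial variance of detections about individual centroids.

    Pools, over individuals with >=2 detections, the squared deviations of
    detection locations (x and y jointly) from each individual's centroid;
    the combined sum of squares is divided by twice the pooled degrees of
    freedom so that on half-normal data RPSV estimates the spatial scale
    sigma itself (the per-axis standard deviation), making 4 x RPSV the
    conventional ~4 sigma buffer.
    """
    xy = history.camera_xy()
    ss = 0.0
    dof = 0
    for i in range(history.n):
        counts = history.y[i].sum(axis=1)  # per camera
        n_det = int(counts.sum())
        if n_det < 2:
            continue
        locs = np.repeat(xy, counts, axis=0)
        cen = locs.mean(axis=0)
        ss += ((locs - cen) ** 2).sum()
        dof += n_det - 1
    if dof == 0:
        raise ParameterError("no individual with >=2 detections; cannot compute RPSV")
    if ss == 0.0:
        raise ParameterError(
            "all recaptures at a single detector (zero spatial variance); "
            "supply a buffer width manually"
        )
    return float(np.sqrt(ss / (2.0 * dof)))


def suggest_buffer(history: CaptureHistory) -> float:
    """Default buffer width: 4 x RPSV of the observed capture locations."""
    return 4.0 * rpsv(history)


# ---------------------------------------------------------------------------
# detection model
# ---------------------------------------------------------------------------

def detection_prob(d, g0: float, sigma: float):
    """Half-normal detection function ``g0 * exp(-d^2 / (2 sigma^2))``."""
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ParameterError("distance must be non-negative")
    out = g0 * np.exp(-(d ** 2) / (2.0 * sigma ** 2))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# model specification and parameter bookkeeping
# ---------------------------------------------------------------------------

VARIANTS = ("null", "sex", "sexhet", "group", "grouphet")


@dataclass(frozen=True)
class SECRModelSpec:
    """Which heterogeneity structure and encounter model to fit."""

    variant: str = "null"
    encounter_model: str = "bernoulli"     # "bernoulli" | "poisson_count"
    n_distribution: str = "poisson"        # "poisson" | "binomial"
    use_coverage: bool = False             # camera coverage as detection offset

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ParameterError(f"unknown variant {self.variant!r}")
        if self.encounter_model not in ("bernoulli", "poisson_count"):
            raise ParameterError(f"unknown encounter model {self.encounter_model!r}")
        if self.n_distribution not in ("poisson", "binomial"):
            raise ParameterError(f"unknown n distribution {self.n_distribution!r}")

    @property
    def known_classes(self) -> tuple[str, ...]:
        if self.variant in ("sex", "sexhet"):
            return ("female", "male")
        if self.variant in ("group", "grouphet"):
            return ("group", "solitary")
        return ("all",)

    @property
    def has_latent_mixture(self) -> bool:
        return self.variant.endswith("het")

    @property
    def n_params(self) -> int:
        base = 3 * len(self.known_classes)
        return base + (3 if self.has_latent_mixture else 0)

    def param_names(self) -> list[str]:
        kc = self.known_classes
        if len(kc) == 1:
            names = ["log_D", "link_g0", "log_sigma"]
        else:
            names = [f"log_D.{c}" for c in kc]
            names += [f"link_g0.{c}" for c in kc]
            names += [f"log_sigma.{c}" for c in kc]
        if self.has_latent_mixture:
            names += ["h2_link_g0", "h2_log_sigma", "logit_pmix"]
        return names


def _invlink_g0(x: np.ndarray, encounter_model: str) -> np.ndarray:
    from scipy.special import expit
    if encounter_model == "bernoulli":
        return expit(x)                      # logit link, g0 in (0, 1)
    return np.exp(np.minimum(x, 700.0))      # log link for lambda0


def _link_g0(g0: float, encounter_model: str) -> float:
    if encounter_model == "bernoulli":
        g0 = min(max(g0, 1e-10), 1 - 1e-10)
        return float(np.log(g0 / (1 - g0)))
    return float(np.log(g0))


@dataclass
class _ClassTable:
    """Expanded (known x latent) detection classes for one parameter point."""

    D: np.ndarray            # density per expanded class (ind/km^2)
    pi: np.ndarray           # latent weight per expanded class (sums to 1 within known)
    g0: np.ndarray
    sigma: np.ndarray
    known_index: np.ndarray  # index into spec.known_classes per expanded class


def _expand_classes(spec: SECRModelSpec, params: np.ndarray,
                    pmix_fixed: float | None = None) -> _ClassTable:
    nk = len(spec.known_classes)
    logD = params[0:nk]
    linkg = params[nk:2 * nk]
    logs = params[2 * nk:3 * nk]
    if spec.has_latent_mixture:
        dg, ds, lpi = params[3 * nk:3 * nk + 3]
        pmix = 1.0 / (1.0 + np.exp(-lpi)) if pmix_fixed is None else pmix_fixed
        D = np.repeat(np.exp(logD), 2)
        pi = np.tile([pmix, 1.0 - pmix], nk)
        g0 = _invlink_g0(np.repeat(linkg, 2) + np.tile([0.0, dg], nk), spec.encounter_model)
        sigma = np.exp(np.repeat(logs, 2) + np.tile([0.0, ds], nk))
        known = np.repeat(np.arange(nk), 2)
    else:
        D = np.exp(logD)
        pi = np.ones(nk)
        g0 = _invlink_g0(linkg, spec.encounter_model)
        sigma = np.exp(logs)
        known = np.arange(nk)
    return _ClassTable(D=D, pi=pi, g0=g0, sigma=sigma, known_index=known)


def _membership(history: CaptureHistory, spec: SECRModelSpec) -> np.ndarray:
    """w[i, j]: may individual i belong to known class j?  Unknown-class
    individuals are allowed in every class (summed over in the likelihood)."""
    nk = len(spec.known_classes)
    w = np.ones((history.n, nk))
    if spec.variant in ("sex", "sexhet"):
        sex = history.covariates["sex"].to_numpy()
        w[:, 0] = (sex != "male")      # female column admits female/unknown
        w[:, 1] = (sex != "female")
    elif spec.variant in ("group", "grouphet"):
        if "solitary" not in history.covariates.columns:
            raise ParameterError(
                "group/grouphet variants need a boolean 'solitary' covariate "
                "(attach one from the co-detection group assignment)"
            )
        sol = history.covariates["solitary"].astype(bool).to_numpy()
        w[:, 0] = ~sol
        w[:, 1] = sol
    return w


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

class _LikelihoodData:
    """Precomputed quantities shared across likelihood evaluations."""

    def __init__(self, history: CaptureHistory, mask: HabitatMask,
                 spec: SECRModelSpec, coverage: np.ndarray | None = None):
        self.history = history
        self.mask = mask
        self.spec = spec
        xy = history.camera_xy()
        diff = xy[:, None, :] - mask.points[None, :, :]
        self.dist2 = (diff ** 2).sum(axis=2)            # (K, M)
        self.effort = history.effort                     # (K, S)
        self.E = self.effort.sum(axis=1)                 # (K,)
        K = len(history.cameras)
        if spec.use_coverage:
            if coverage is None:
                raise ParameterError("spec.use_coverage set but no coverage given")
            self.cov = np.asarray(coverage, dtype=float)
        else:
            self.cov = np.ones(K)
        self.w = _membership(history, spec)
        n = history.n
        if spec.encounter_model == "bernoulli":
            det = np.argwhere(history.y > 0)             # rows (i, k, s)
            pairs = sorted({(k, s) for _, k, s in det})
            self.pair_index = {p: u for u, p in enumerate(pairs)}
            self.pairs = np.array(pairs, dtype=int).reshape(-1, 2)
            rows = [self.pair_index[(k, s)] for _, k, s in det]
            A = sparse.csr_matrix(
                (np.ones(len(det)), (det[:, 0], rows)), shape=(n, len(pairs))
            )
            self.A = A
            self.e_pairs = self.effort[self.pairs[:, 0], self.pairs[:, 1]] \
                if len(pairs) else np.zeros(0)
        else:
            counts = history.y.sum(axis=2)               # (n, K)
            self.Ak = sparse.csr_matrix(counts.astype(float))
            # per-individual constants: sum_ks y*log(e) - log(y!)
            const = np.zeros(n)
            y = history.y
            nz = np.argwhere(y > 0)
            for i, k, s in nz:
                e = self.effort[k, s]
                if e <= 0:
                    raise ParameterError(
                        "detection recorded where effort is zero"
                    )
                const[i] += y[i, k, s] * np.log(e) - lgamma(y[i, k, s] + 1.0)
            self.const = const

    # ---- per-class pieces ----------------------------------------------

    def class_terms(self, g0: float, sigma: float):
        """Return (log_pr, pdot): log Pr(history_i | centre m) as an (n, M)
        array and the per-cell probability of being detected at all."""
        h = np.exp(-self.dist2 / (2.0 * sigma * sigma))
        if self.spec.encounter_model == "bernoulli":
            g = np.clip(g0 * self.cov[:, None] * h, 0.0, 1.0 - 1e-12)
            l1m = np.log1p(-g)                                 # (K, M)
            base = self.E @ l1m                                # (M,)
            pdot = -np.expm1(base)
            if len(self.pairs):
                lk = l1m[self.pairs[:, 0]] * self.e_pairs[:, None]   # (U, M)
                with np.errstate(divide="ignore"):
                    lp = np.log(-np.expm1(lk)) - lk
                add = self.A @ lp                              # (n, M)
            else:
                add = np.zeros((self.history.n, self.mask.n_cells))
            log_pr = base[None, :] + add
        else:
            lam = g0 * self.cov[:, None] * h                   # (K, M)
            Lam = self.E @ lam                                 # (M,)
            pdot = -np.expm1(-Lam)
            with np.errstate(divide="ignore"):
                loglam = np.log(lam)
            add = self.Ak @ loglam                             # (n, M)
            log_pr = -Lam[None, :] + add + self.const[:, None]
        return log_pr, pdot


def neg_log_likelihood(params: np.ndarray, data: _LikelihoodData,
                       pmix_fixed: float | None = None) -> float:
    """Negative log of the Poisson-process full likelihood.

    logL = -Lambda + sum_i log( a * sum_m sum_c w_ic D_c pi_c Pr(w_i|m,c) )
    with Lambda = a * sum_m sum_c D_c pi_c pdot_c(m).  For the binomial
    n-distribution the Poisson count term on n is replaced by a binomial
    with super-population size N = D_total * A.
    """
    spec, mask = data.spec, data.mask
    params = np.asarray(params, dtype=float)
    try:
        table = _expand_classes(spec, params, pmix_fixed=pmix_fixed)
    except FloatingPointError:
        return np.inf
    a = mask.cell_area_km2
    n, M = data.history.n, mask.n_cells
    numer = np.zeros((n, M))
    Lam = 0.0
    pieces = []
    for c in range(len(table.D)):
        log_pr, pdot = data.class_terms(table.g0[c], table.sigma[c])
        weight = table.D[c] * table.pi[c]
        Lam += a * weight * pdot.sum()
        pieces.append((log_pr, weight, table.known_index[c]))
    # stabilised per-individual sum over classes and cells; the shift only
    # looks at classes the individual may belong to, else admissible-class
    # terms can underflow to zero and fake an impossible history
    shift = np.full(n, -np.inf)
    for log_pr, _, kidx in pieces:
        rowmax = np.where(data.w[:, kidx] > 0, log_pr.max(axis=1), -np.inf)
        shift = np.maximum(shift, rowmax)
    shift[~np.isfinite(shift)] = 0.0
    for log_pr, weight, kidx in pieces:
        admissible = data.w[:, kidx] > 0
        if not admissible.any():
            continue
        numer[admissible] += weight * np.exp(
            log_pr[admissible] - shift[admissible, None])
    if not np.isfinite(Lam):
        return np.inf
    if Lam <= 0.0 and n > 0:
        # no detection is possible anywhere: a nonempty history has
        # probability zero
        return np.inf
    sums = numer.sum(axis=1)
    # floor underflowed numerators: keeps the surface finite (and steeply
    # unfavourable) at near-impossible parameter corners, which bounded
    # quasi-Newton line searches must be able to evaluate
    log_numer = np.log(a) + shift + np.log(np.maximum(sums, 1e-300))
    if spec.n_distribution == "poisson":
        ll = -Lam + log_numer.sum()
    else:
        # binomial n-distribution: N individuals on the mask, each detected
        # with probability Lambda / N (continuous N via gammaln)
        N = float((table.D * table.pi).sum() * mask.area_km2)
        if N <= n or Lam >= N:
            return np.inf
        p = Lam / N
        ll = (
            log_numer.sum() - n * np.log(Lam)
            + lgamma(N + 1.0) - lgamma(N - n + 1.0) - lgamma(n + 1.0)
            + n * np.log(p) + (N - n) * np.log1p(-p)
        )
    return -ll if np.isfinite(ll) else np.inf


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class SECRFit:
    """A fitted SECR model: link-scale estimates, covariance and summaries."""

    spec: SECRModelSpec
    params: np.ndarray
    param_names: list[str]
    loglik: float
    n: int
    converged: bool
    vcov: np.ndarray | None = None
    mask: HabitatMask | None = None
    message: str = ""

    @property
    def k(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik

    @property
    def aicc(self) -> float | None:
        if self.n <= self.k + 1:
            return None
        return self.aic + 2 * self.k * (self.k + 1) / (self.n - self.k - 1)

    # ---- derived quantities -------------------------------------------

    def _d_indices(self) -> list[int]:
        return [i for i, nm in enumerate(self.param_names) if nm.startswith("log_D")]

    def density(self) -> dict:
        """Total density (ind/km^2) with SE and a log-normal-style 95% CI."""
        di = self._d_indices()
        Dc = np.exp(self.params[di])
        D = float(Dc.sum())
        se = cil = cih = None
        if self.vcov is not None:
            grad = np.zeros(self.k)
            grad[di] = Dc                      # d(sum exp)/d(logD_c)
            var = float(grad @ self.vcov @ grad)
            if var >= 0:
                se = float(np.sqrt(var))
                cil, cih = _lognormal_ci(D, se)
        out = {"estimate": D, "se": se, "ci_low": cil, "ci_high": cih}
        if len(di) > 1:
            for nm, val in zip([self.param_names[i] for i in di], Dc):
                out[nm.replace("log_D.", "D.")] = float(val)
        return out

    def sigma(self, cls: int = 0) -> dict:
        """Spatial scale (m) for a known class, with Wald CI on the log scale."""
        nk = len(self.spec.known_classes)
        idx = 2 * nk + cls
        s = float(np.exp(self.params[idx]))
        cil = cih = se = None
        if self.vcov is not None and self.vcov[idx, idx] >= 0:
            sd = float(np.sqrt(self.vcov[idx, idx]))
            se = s * sd
            cil, cih = s * np.exp(-_Z95 * sd), s * np.exp(_Z95 * sd)
        return {"estimate": s, "se": se, "ci_low": cil, "ci_high": cih}

    def estimates(self) -> pd.DataFrame:
        """Back-transformed natural-scale parameter table with 95% Wald CIs."""
        rows = []
        for i, nm in enumerate(self.param_names):
            est = self.params[i]
            se = np.sqrt(self.vcov[i, i]) if self.vcov is not None else np.nan
            lo, hi = est - _Z95 * se, est + _Z95 * se
            if nm.startswith(("log_D", "log_sigma", "h2_log")):
                f = np.exp
            elif nm.startswith("link_g0") or nm == "h2_link_g0":
                f = (lambda x: 1 / (1 + np.exp(-x))) \
                    if self.spec.encounter_model == "bernoulli" else np.exp
            elif nm == "logit_pmix":
                f = lambda x: 1 / (1 + np.exp(-x))
            else:
                f = lambda x: x
            rows.append({
                "parameter": nm, "link_estimate": est, "link_se": se,
                "estimate": float(f(est)), "ci_low": float(f(lo)),
                "ci_high": float(f(hi)),
            })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        aicc = self.aicc
        return {
            "variant": self.spec.variant,
            "encounter_model": self.spec.encounter_model,
            "n_distribution": self.spec.n_distribution,
            "param_names": self.param_names,
            "link_params": [float(p) for p in self.params],
            "logLik": self.loglik,
            "k": self.k,
            "n": self.n,
            "AIC": self.aic,
            "AICc": aicc,
            "converged": self.converged,
            "density": self.density(),
        }


def _lognormal_ci(est: float, se: float) -> tuple[float, float]:
    """Asymmetric CI treating the estimate as log-normally distributed."""
    if est <= 0:
        return (np.nan, np.nan)
    cv2 = (se / est) ** 2
    C = np.exp(_Z95 * np.sqrt(np.log(1 + cv2)))
    return float(est / C), float(est * C)


def default_start(history: CaptureHistory, mask: HabitatMask,
                  spec: SECRModelSpec) -> np.ndarray:
    """Fixed default start: naive density n/area, g0 = 0.1 (lambda0 = 0.3),
    sigma from RPSV (falling back to a quarter of the buffer)."""
    nk = len(spec.known_classes)
    D0 = max(history.n / mask.area_km2, 1e-3) / nk
    try:
        s0 = rpsv(history)
    except ParameterError:
        s0 = mask.buffer_m / 4.0
    g0 = 0.1 if spec.encounter_model == "bernoulli" else 0.3
    start = [np.log(D0)] * nk + [_link_g0(g0, spec.encounter_model)] * nk \
        + [np.log(s0)] * nk
    if spec.has_latent_mixture:
        start += [-0.5 if spec.encounter_model == "bernoulli" else -0.5, 0.5, 0.0]
    return np.array(start)


def fit_secr(history: CaptureHistory, mask: HabitatMask, spec: SECRModelSpec,
             start: np.ndarray | None = None, coverage: np.ndarray | None = None,
             n_restarts: int = 3, seed: int = 0, tol: float = 1e-11) -> SECRFit:
    """Maximise the SECR likelihood on the link scale (L-BFGS-B).

    ``n_restarts`` jittered restarts guard against local optima; the best
    converged solution wins.  Standard errors come from the inverse of a
    central-difference Hessian at the optimum.  Deterministic given
    ``seed``, the start point and the data.
    """
    if history.n < 1:
        raise ParameterError("capture history has no individuals")
    data = _LikelihoodData(history, mask, spec, coverage=coverage)
    x0 = default_start(history, mask, spec) if start is None else np.asarray(start, float)
    rng = np.random.default_rng(seed)
    best = None
    # box bounds keep the optimiser away from degenerate corners (densities
    # or scales running off to infinity, latent "ghost" classes with
    # absurd sigma soaking up density mass)
    extent = np.ptp(mask.points, axis=0).max() + 2 * mask.spacing_m
    nk = len(spec.known_classes)
    bounds = (
        [(-12.0, 8.0)] * nk
        + [(-14.0, 8.0)] * nk
        + [(np.log(mask.spacing_m / 10.0), np.log(3.0 * extent))] * nk
    )
    if spec.has_latent_mixture:
        bounds += [(-5.0, 5.0), (-2.5, 2.5), (-5.0, 5.0)]
    x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
    starts = [x0]
    if spec.has_latent_mixture:
        # finite mixtures are multimodal: always try a well-separated
        # second class (low-rate minority) alongside the neutral start
        x1 = x0.copy()
        x1[-3:] = [-1.9, 0.0, 0.85]
        starts.append(x1)
    starts += [np.clip(x0 + rng.normal(0.0, 0.25, size=len(x0)),
                       [b[0] for b in bounds], [b[1] for b in bounds])
               for _ in range(max(0, n_restarts - 1))]
    for s in starts:
        res = optimize.minimize(
            neg_log_likelihood, s, args=(data,), method="L-BFGS-B",
            bounds=bounds,
            # ftol is relative; 1e-11 of a log-likelihood of O(1e3) is an
            # absolute tolerance around 1e-8
            options={"maxiter": 1000, "ftol": tol, "gtol": 1e-6},
        )
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    if best is None:
        return SECRFit(spec=spec, params=x0, param_names=spec.param_names(),
                       loglik=-np.inf, n=history.n, converged=False,
                       mask=mask, message="no finite likelihood found")
    vcov = None
    hess = _numeric_hessian(lambda p: neg_log_likelihood(p, data), best.x)
    try:
        vcov = np.linalg.inv(hess)
        if not np.all(np.isfinite(vcov)) or np.any(np.diag(vcov) < 0):
            vcov = None
    except np.linalg.LinAlgError:
        vcov = None
    return SECRFit(
        spec=spec, params=best.x, param_names=spec.param_names(),
        loglik=-float(best.fun), n=history.n, converged=bool(best.success),
        vcov=vcov, mask=mask, message=str(best.message),
    )


def _numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    k = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


# ---------------------------------------------------------------------------
# model comparison and derived quantities
# ---------------------------------------------------------------------------

def compare_models(fits: Sequence[SECRFit]) -> pd.DataFrame:
    """AICc model table with dAICc and Akaike weights.

    All fits must be on the same data (checked via n).  Fits whose AICc is
    undefined (n <= k+1) are reported with missing AICc and zero weight.
    """
    if not fits:
        raise ParameterError("no fits to compare")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ParameterError("fits compare different data (unequal n)")
    rows = []
    for f in fits:
        rows.append({
            "model": f.spec.variant, "npar": f.k, "logLik": f.loglik,
            "AIC": f.aic, "AICc": f.aicc if f.aicc is not None else np.nan,
        })
    tab = pd.DataFrame(rows)
    finite = tab["AICc"].notna()
    best = tab.loc[finite, "AICc"].min()
    tab["dAICc"] = tab["AICc"] - best
    w = np.where(finite, np.exp(-0.5 * tab["dAICc"].fillna(np.inf)), 0.0)
    tab["AICwt"] = w / w.sum()
    return tab.sort_values("AICc", na_position="last").reset_index(drop=True)


def akaike_weights(aicc: Sequence[float]) -> np.ndarray:
    """Normalised Akaike weights exp(-dAICc/2) for a set of AICc values."""
    a = np.asarray(aicc, dtype=float)
    w = np.exp(-0.5 * (a - np.nanmin(a)))
    w = np.where(np.isnan(w), 0.0, w)
    return w / w.sum()


def region_abundance(fit: SECRFit, region_area_km2: float) -> dict:
    """Expected number of activity centres in a region of the given area."""
    if region_area_km2 < 0:
        raise ParameterError("region area must be non-negative")
    if not fit.converged:
        raise ParameterError("fit did not converge; no abundance available")
    d = fit.density()
    out = {"estimate": d["estimate"] * region_area_km2}
    for key in ("ci_low", "ci_high"):
        out[key] = d[key] * region_area_km2 if d[key] is not None else None
    return out


def circular_r95(sigma_m: float, sigma_ci: tuple[float, float] | None = None) -> dict:
    """95% home-range radius (m) and circular area (km^2) from sigma.

    r95 = sigma * sqrt(chi2_0.95(2)); area = pi * r95^2.  A CI on sigma is
    transformed endpoint-wise (both maps are monotone).
    """
    if sigma_m <= 0:
        raise ParameterError("sigma must be positive")
    r = sigma_m * R95_FACTOR
    out = {"r95_m": float(r), "area_km2": float(np.pi * r ** 2 / M2_PER_KM2)}
    if sigma_ci is not None:
        lo, hi = sigma_ci
        rlo, rhi = lo * R95_FACTOR, hi * R95_FACTOR
        out["r95_ci_m"] = (float(rlo), float(rhi))
        out["area_ci_km2"] = (
            float(np.pi * rlo ** 2 / M2_PER_KM2),
            float(np.pi * rhi ** 2 / M2_PER_KM2),
        )
    return out


def precision(estimate: float, ci_low: float, ci_high: float) -> int:
    """Relative CI width: full 95% CI width over the estimate, as a rounded
    percentage (smaller is more precise)."""
    if estimate == 0:
        raise ParameterError("precision undefined for a zero estimate")
    if not (ci_low <= estimate <= ci_high):
        raise ParameterError("need ci_low <= estimate <= ci_high")
    return int(round(100.0 * (ci_high - ci_low) / estimate))
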