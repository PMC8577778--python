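"""Debye dielectric models for homogenized insect tissue.

The complex relative permittivity of the homogenized mosquito mixture is
described by a multi-relaxation Debye model with a static conduction term,

.. math::

    \\hat\\epsilon(\\omega) = \\epsilon' - j\\epsilon''
        = \\epsilon_\\infty
        + \\sum_i \\frac{\\Delta\\epsilon_i}{1 + j\\omega\\tau_i}
        - j\\frac{\\sigma_s}{\\omega\\epsilon_0},

so that

.. math::

    \\epsilon'(\\omega) = \\epsilon_\\infty
        + \\sum_i \\frac{\\Delta\\epsilon_i}{1 + (\\omega\\tau_i)^2},
    \\qquad
    \\epsilon''(\\omega) = \\frac{\\sigma_s}{\\omega\\epsilon_0}
        + \\sum_i \\frac{\\Delta\\epsilon_i\\,\\omega\\tau_i}{1 + (\\omega\\tau_i)^2}.

Conductivity and loss factor are interchangeable through
:math:`\\epsilon'' = \\sigma / (\\omega\\epsilon_0)`.

Two reference parameter sets for *Aedes aegypti* (22 degC homogenate,
open-coaxial-probe spectroscopy over 5-67 GHz, two relaxations) ship as
:data:`AEDES_FIT2_EPS` for the real part and :data:`AEDES_FIT2_SIGMA` for
the conductivity / loss factor.  The two quantities were tabulated from
independent least-squares fits, so the pipeline evaluates each from its
own row; :func:`fit_debye` supports both that split mode and a joint fit.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from aedosim.constants import C0, EPS0

__all__ = [
    "DebyeParameters",
    "PermittivitySpectrum",
    "FitResult",
    "FitError",
    "evaluate_debye",
    "loss_to_conductivity",
    "conductivity_to_loss",
    "wavelength_in_medium",
    "dak_tl_grid",
    "fit_debye",
    "debye_spectrum",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "AEDES_FIT2_EPS",
    "AEDES_FIT2_SIGMA",
    "NAMED_PARAMETER_SETS",
]


class FitError(RuntimeError):
    """Raised when a Debye fit cannot be performed or did not converge.

    ``best`` carries the best iterate found (a :class:`FitResult` or
    ``None``) so callers can inspect partial progress.
    """

    def __init__(self, message: str, best: "FitResult | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class DebyeParameters:
    """Parameters of a multi-relaxation Debye model with static conduction.

    Parameters
    ----------
    eps_inf
        Relative permittivity in the infinite-frequency limit.  ``None``
        marks a loss-only parameter set (e.g. a conductivity fit that
        never tabulated eps_inf); such a set cannot evaluate eps_real.
    relaxations
        Sequence of ``(delta_eps, tau)`` pairs, tau in seconds.  Stored
        sorted by descending relaxation time.
    sigma_s
        Static (ionic) conductivity in S/m.
    """

    eps_inf: float | None
    relaxations: tuple[tuple[float, float], ...]
    sigma_s: float = 0.0

    def __post_init__(self):
        if self.eps_inf is not None and not self.eps_inf > 0:
            raise ValueError(f"eps_inf must be positive, got {self.eps_inf}")
        rel = tuple(
            (float(d), float(t))
            for d, t in sorted(self.relaxations, key=lambda r: -r[1])
        )
        for d, t in rel:
            if d < 0:
                raise ValueError(f"delta_eps must be >= 0, got {d}")
            if not t > 0:
                raise ValueError(f"tau must be positive, got {t}")
        if self.sigma_s < 0:
            raise ValueError(f"sigma_s must be >= 0, got {self.sigma_s}")
        object.__setattr__(self, "relaxations", rel)

    @property
    def n_relaxations(self) -> int:
        return len(self.relaxations)

    def with_sigma_s(self, sigma_s: float) -> "DebyeParameters":
        return replace(self, sigma_s=sigma_s)


@dataclass
class PermittivitySpectrum:
    """A sampled complex-permittivity spectrum.

    ``frequencies`` (Hz, strictly increasing), ``eps_real`` and ``sigma``
    (S/m) are equal-length 1-D arrays.  ``temperature`` is the sample
    temperature in degrees Celsius and ``provenance`` is one of
    ``"measured"``, ``"synthetic"`` or ``"extrapolated"``.
    """

    frequencies: np.ndarray
    eps_real: np.ndarray
    sigma: np.ndarray
    temperature: float = 22.0
    provenance: str = "measured"

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.eps_real = np.asarray(self.eps_real, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = self.frequencies.size
        if self.eps_real.size != n or self.sigma.size != n:
            raise ValueError("frequency, eps_real and sigma arrays must have equal length")
        if n and not np.all(np.diff(self.frequencies) > 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.frequencies <= 0):
            raise ValueError("frequencies must be positive")
        if np.any(self.eps_real <= 0):
            raise ValueError("eps_real must be positive")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be nonnegative")
        if self.provenance not in ("measured", "synthetic", "extrapolated"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def __len__(self) -> int:
        return self.frequencies.size

    @property
    def eps_imag(self) -> np.ndarray:
        """Loss factor derived from the conductivity column."""
        return conductivity_to_loss(self.sigma, self.frequencies)


@dataclass
class FitResult:
    """Outcome of a Debye least-squares fit.

    In ``separate`` mode ``params_eps`` and ``params_sigma`` come from
    independent fits of the real part and the conductivity (mirroring
    the two tabulated rows of the reference data set); in ``joint`` mode
    they are the same object.  ``params`` aliases ``params_eps``.
    """

    params_eps: DebyeParameters
    params_sigma: DebyeParameters
    r_squared_real: float
    r_squared_sigma: float
    residuals_real: np.ndarray = field(repr=False)
    residuals_sigma: np.ndarray = field(repr=False)
    mode: str = "separate"
    n_relaxations: int = 2

    def __post_init__(self):
        if self.r_squared_real > 1 + 1e-12 or self.r_squared_sigma > 1 + 1e-12:
            raise ValueError("R^2 cannot exceed 1")

    @property
    def params(self) -> DebyeParameters:
        return self.params_eps


# --- Reference parameter sets (A. aegypti homogenate, two relaxations) ----

#: Real-part row of the two-relaxation fit: eps'(f).
AEDES_FIT2_EPS = DebyeParameters(
    eps_inf=4.544,
    relaxations=((4.978, 3.493e-12), (13.24, 14.68e-12)),
    sigma_s=0.0,
)

#: Conductivity row of the two-relaxation fit: sigma(f) / loss factor.
#: The tabulated conductivity fit carries no eps_inf (the loss model does
#: not contain it), hence ``eps_inf=None``.
AEDES_FIT2_SIGMA = DebyeParameters(
    eps_inf=None,
    relaxations=((4.213, 2.477e-12), (12.89, 12.23e-12)),
    sigma_s=1.297,
)

NAMED_PARAMETER_SETS: dict[str, DebyeParameters] = {
    "aedes_fit2_eps": AEDES_FIT2_EPS,
    "aedes_fit2_sigma": AEDES_FIT2_SIGMA,
}


# --- Evaluation ------------------------------------------------------------

def _check_positive_frequency(f) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    return f


def evaluate_debye(params: DebyeParameters, f):
    """Evaluate a Debye model at frequency ``f`` (Hz, scalar or array).

    Returns ``(eps_real, eps_imag, sigma)``.  For a loss-only parameter
    set (``eps_inf is None``) ``eps_real`` is NaN.
    """
    f = _check_positive_frequency(f)
    w = 2.0 * np.pi * f
    eps_real = np.full_like(w, np.nan) if params.eps_inf is None else np.full_like(w, params.eps_inf)
    eps_imag = params.sigma_s / (w * EPS0)
    for delta, tau in params.relaxations:
        wt = w * tau
        denom = 1.0 + wt * wt
        if params.eps_inf is not None:
            eps_real = eps_real + delta / denom
        eps_imag = eps_imag + delta * wt / denom
    sigma = eps_imag * w * EPS0
    if np.isscalar(f) or f.ndim == 0:
        return float(eps_real), float(eps_imag), float(sigma)
    return eps_real, eps_imag, sigma


def loss_to_conductivity(eps_imag, f):
    """Convert loss factor eps'' to conductivity via sigma = eps'' * omega * eps0."""
    f = _check_positive_frequency(f)
    return np.asarray(eps_imag, dtype=float) * 2.0 * np.pi * f * EPS0


def conductivity_to_loss(sigma, f):
    """Convert conductivity (S/m) to loss factor eps'' = sigma / (omega * eps0)."""
    f = _check_positive_frequency(f)
    return np.asarray(sigma, dtype=float) / (2.0 * np.pi * f * EPS0)


def wavelength_in_medium(f, eps_real):
    """In-medium wavelength lambda = c / (f * sqrt(eps_real)), in meters."""
    f = np.asarray(f, dtype=float)
    eps_real = np.asarray(eps_real, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    if np.any(eps_real <= 0):
        raise ValueError("eps_real must be positive")
    return C0 / (f * np.sqrt(eps_real))


def dak_tl_grid() -> np.ndarray:
    """The open-coaxial-probe measurement grid (Hz).

    5.00-6.00 GHz inclusive in 50 MHz steps (21 points) followed by
    6.25-67.00 GHz in 250 MHz steps (244 points); 265 points total.
    """
    low = 5.0e9 + 50.0e6 * np.arange(21)
    high = 6.25e9 + 250.0e6 * np.arange(244)
    return np.concatenate([low, high])


def debye_spectrum(
    eps_params: DebyeParameters,
    sigma_params: DebyeParameters | None = None,
    frequencies=None,
    temperature: float = 22.0,
    provenance: str = "extrapolated",
) -> PermittivitySpectrum:
    """Evaluate Debye rows on a frequency grid as a :class:`PermittivitySpectrum`.

    ``eps_params`` supplies the real part; ``sigma_params`` supplies the
    conductivity (defaults to ``eps_params``, i.e. a single consistent
    model).
    """
    if frequencies is None:
        frequencies = dak_tl_grid()
    frequencies = np.asarray(frequencies, dtype=float)
    eps_real, _, _ = evaluate_debye(eps_params, frequencies)
    _, _, sigma = evaluate_debye(sigma_params or eps_params, frequencies)
    return PermittivitySpectrum(
        frequencies=frequencies,
        eps_real=eps_real,
        sigma=sigma,
        temperature=temperature,
        provenance=provenance,
    )


# --- Fitting ---------------------------------------------------------------

_TAU_LO = 0.1e-12
_TAU_HI = 100e-12


def _eps_real_model(theta, w, n_rel):
    # theta = [eps_inf, d1, log_tau1, d2, log_tau2, ...]
    out = np.full_like(w, theta[0])
    for i in range(n_rel):
        d = theta[1 + 2 * i]
        tau = np.exp(theta[2 + 2 * i])
        out = out + d / (1.0 + (w * tau) ** 2)
    return out


def _sigma_model(theta, w, n_rel):
    # theta = [sigma_s, d1, log_tau1, ...]; sigma = eps'' * w * eps0
    out = np.full_like(w, theta[0])
    for i in range(n_rel):
        d = theta[1 + 2 * i]
        tau = np.exp(theta[2 + 2 * i])
        out = out + EPS0 * d * w * w * tau / (1.0 + (w * tau) ** 2)
    return out


def _r_squared(observed, predicted) -> float:
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - np.mean(observed)) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    return 1.0 - ss_res / ss_tot


def _tau_starts(n_rel: int, n_starts: int, rng: np.random.Generator):
    """Log-spaced relaxation-time initializations with a little seeded jitter.

    Multi-start avoids label swapping between relaxations and escapes the
    shallow local minima of the two-time-constant model.
    """
    base = np.logspace(np.log10(_TAU_LO * 2), np.log10(_TAU_HI / 2), 6)
    starts = []
    for k in range(n_starts):
        jitter = rng.uniform(0.7, 1.4, size=n_rel) if k else np.ones(n_rel)
        if n_rel == 1:
            taus = [base[k % len(base)]]
        else:
            i = k % (len(base) - 1)
            taus = [base[i], base[min(i + 2, len(base) - 1)]]
        starts.append(np.sort(np.asarray(taus) * jitter))
    return starts


def _fit_single(observed, w, n_rel, model, head_init, head_bounds, rng, n_starts):
    scale = np.where(observed != 0, np.abs(observed), 1.0)

    def resid(theta):
        return (model(theta, w, n_rel) - observed) / scale

    lo = [head_bounds[0]] + [0.0, np.log(_TAU_LO)] * n_rel
    hi = [head_bounds[1]] + [1e3, np.log(_TAU_HI)] * n_rel
    d_init = max(float(np.ptp(observed)), 1e-3)
    best = None
    for taus in _tau_starts(n_rel, n_starts, rng):
        theta0 = [head_init]
        for t in taus:
            theta0 += [d_init / n_rel, np.log(t)]
        theta0 = np.clip(theta0, lo, hi)
        try:
            res = least_squares(resid, theta0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14)
        except Exception:  # pragma: no cover - scipy-internal failure
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("all least-squares starts failed")
    return best


def _unpack(theta, n_rel):
    head = float(theta[0])
    rel = tuple(
        (float(theta[1 + 2 * i]), float(np.exp(theta[2 + 2 * i])))
        for i in range(n_rel)
    )
    return head, rel


def fit_debye(
    spectrum: PermittivitySpectrum,
    n_relaxations: int = 2,
    mode: str = "separate",
    seed: int = 0,
    n_starts: int = 8,
) -> FitResult:
    """Fit a Debye model to a measured/synthetic spectrum.

    ``mode="separate"`` (default) fits the real part and the conductivity
    independently, yielding two parameter rows as the reference data set
    tabulates them.  ``mode="joint"`` shares the relaxation strengths and
    times between both observables and fits a single parameter set.
    Residuals are relative (divided by the observed value) so the two
    observables contribute on comparable scales.  Deterministic for a
    fixed ``seed``.
    """
    if n_relaxations not in (1, 2):
        raise ValueError("n_relaxations must be 1 or 2")
    if mode not in ("separate", "joint"):
        raise ValueError("mode must be 'separate' or 'joint'")
    n_free = 2 + 2 * n_relaxations  # per-observable free parameters
    if len(spectrum) < 3 * n_free:
        raise FitError(
            f"need at least {3 * n_free} points to fit {n_relaxations} "
            f"relaxation(s); spectrum has {len(spectrum)}"
        )
    if np.ptp(spectrum.eps_real) < 1e-12 * np.abs(spectrum.eps_real).max() and \
       np.ptp(spectrum.sigma) < 1e-12 * max(np.abs(spectrum.sigma).max(), 1.0):
        raise FitError("degenerate (constant) spectrum")

    w = 2.0 * np.pi * spectrum.frequencies
    rng = np.random.default_rng(seed)

    if mode == "separate":
        res_e = _fit_single(
            spectrum.eps_real, w, n_relaxations, _eps_real_model,
            head_init=float(spectrum.eps_real[-1]), head_bounds=(1e-6, 1e3),
            rng=rng, n_starts=n_starts,
        )
        res_s = _fit_single(
            spectrum.sigma, w, n_relaxations, _sigma_model,
            head_init=max(float(spectrum.sigma[0]) * 0.5, 1e-6),
            head_bounds=(0.0, 1e3), rng=rng, n_starts=n_starts,
        )
        eps_inf, rel_e = _unpack(res_e.x, n_relaxations)
        sigma_s, rel_s = _unpack(res_s.x, n_relaxations)
        params_eps = DebyeParameters(eps_inf=eps_inf, relaxations=rel_e, sigma_s=0.0)
        params_sigma = DebyeParameters(eps_inf=None, relaxations=rel_s, sigma_s=sigma_s)
        pred_e = _eps_real_model(res_e.x, w, n_relaxations)
        pred_s = _sigma_model(res_s.x, w, n_relaxations)
    else:
        scale_e = np.abs(spectrum.eps_real)
        scale_s = np.where(spectrum.sigma != 0, np.abs(spectrum.sigma), 1.0)

        def resid(theta):
            # theta = [eps_inf, sigma_s, d1, log_tau1, ...]
            th_e = np.concatenate([[theta[0]], theta[2:]])
            th_s = np.concatenate([[theta[1]], theta[2:]])
            re = (_eps_real_model(th_e, w, n_relaxations) - spectrum.eps_real) / scale_e
            rs = (_sigma_model(th_s, w, n_relaxations) - spectrum.sigma) / scale_s
            return np.concatenate([re, rs])

        lo = [1e-6, 0.0] + [0.0, np.log(_TAU_LO)] * n_relaxations
        hi = [1e3, 1e3] + [1e3, np.log(_TAU_HI)] * n_relaxations
        d_init = max(float(np.ptp(spectrum.eps_real)), 1e-3)
        best = None
        for taus in _tau_starts(n_relaxations, n_starts, rng):
            theta0 = [float(spectrum.eps_real[-1]), max(float(spectrum.sigma[0]) * 0.5, 1e-6)]
            for t in taus:
                theta0 += [d_init / n_relaxations, np.log(t)]
            theta0 = np.clip(theta0, lo, hi)
            res = least_squares(resid, theta0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14)
            if best is None or res.cost < best.cost:
                best = res
        eps_inf = float(best.x[0])
        sigma_s = float(best.x[1])
        _, rel = _unpack(np.concatenate([[0.0], best.x[2:]]), n_relaxations)
        params_eps = params_sigma = DebyeParameters(
            eps_inf=eps_inf, relaxations=rel, sigma_s=sigma_s
        )
        pred_e = _eps_real_model(np.concatenate([[eps_inf], best.x[2:]]), w, n_relaxations)
        pred_s = _sigma_model(np.concatenate([[sigma_s], best.x[2:]]), w, n_relaxations)

    result = FitResult(
        params_eps=params_eps,
        params_sigma=params_sigma,
        r_squared_real=_r_squared(spectrum.eps_real, pred_e),
        r_squared_sigma=_r_squared(spectrum.sigma, pred_s),
        residuals_real=pred_e - spectrum.eps_real,
        residuals_sigma=pred_s - spectrum.sigma,
        mode=mode,
        n_relaxations=n_relaxations,
    )
    if result.r_squared_real < 0.5 or result.r_squared_sigma < 0.5:
        raise FitError(
            f"fit did not converge to a descriptive model "
            f"(R^2={result.r_squared_real:.3g}/{result.r_squared_sigma:.3g})",
            best=result,
        )
    return result


# --- Spectrum CSV I/O ------------------------------------------------------

_CSV_COLUMNS = ["frequency_hz", "eps_real", "sigma_s_per_m"]


def write_spectrum_csv(spectrum: PermittivitySpectrum, path) -> None:
    """Write a spectrum as CSV with a ``# temperature_c`` metadata line."""
    df = pd.DataFrame(
        {
            "frequency_hz": spectrum.frequencies,
            "eps_real": spectrum.eps_real,
            "sigma_s_per_m": spectrum.sigma,
        }
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# temperature_c: {spectrum.temperature}\n")
        fh.write(f"# provenance: {spectrum.provenance}\n")
        df.to_csv(fh, index=False)


def read_spectrum_csv(path) -> PermittivitySpectrum:
    """Read a spectrum CSV (columns ``frequency_hz, eps_real, sigma_s_per_m``)."""
    temperature = 22.0
    provenance = "measured"
    lines = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("temperature_c"):
                    temperature = float(body.split(":", 1)[1])
                elif body.startswith("provenance"):
                    provenance = body.split(":", 1)[1].strip()
            else:
                lines.append(line)
    df = pd.read_csv(io.StringIO("".join(lines)))
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spectrum CSV is missing column(s): {', '.join(missing)}")
    return PermittivitySpectrum(
        frequencies=df["frequency_hz"].to_numpy(),
        eps_real=df["eps_real"].to_numpy(),
        sigma=df["sigma_s_per_m"].to_numpy(),
        temperature=temperature,
        provenance=provenance,
    )
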