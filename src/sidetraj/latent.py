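"""Exact transition laws for the latent continuous-time processes.

Two stochastic differential equations are supported for the latent
(unbounded) ideation state x(t):

* Wiener process (continuous-time random walk):
  ``dx = exp(phi2) dW``.  The conditional law over a gap of ``dt`` days is
  ``N(x0, exp(2*phi2) * dt)``.
* Ornstein-Uhlenbeck process (continuous-time autoregression):
  ``dx = exp(phi3) * (phi4 - x) dt + exp(phi2) dW``, mean-reverting towards
  the long-term constant ``phi4`` at rate ``theta = exp(phi3)`` per day.

Both transitions are exact at arbitrary irregular gaps, so no Euler
discretisation error enters anywhere in the package.  Parameters live on
unbounded scales so that hierarchical normal random effects are well formed:
``phi2`` is the log of the diffusion SD per sqrt(day) and ``phi3`` the log
mean-reversion rate per day.  Time is measured in days throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GaussianMoments",
    "ModelSpec",
    "IndividualParams",
    "wiener_transition",
    "ou_transition",
    "simulate_latent_path",
]

#: Table-style model variants: (model_type, per-slot random-effect flags).
#: Slots are ordered (baseline, diffusion) for Wiener and
#: (baseline, diffusion, drift-rate, constant) for OU.  Variant ids increase
#: with the number of free parameters within each model type.
_VARIANTS = {
    1: ("wiener", (True, False)),
    2: ("wiener", (True, True)),
    3: ("ou", (True, True, False, True)),
    4: ("ou", (True, True, True, True)),
}


@dataclass(frozen=True)
class GaussianMoments:
    """Mean and variance of a Gaussian transition density (latent units)."""

    mean: np.ndarray | float
    variance: np.ndarray | float


@dataclass(frozen=True)
class ModelSpec:
    """Which latent process is used and which parameters are random effects.

    Parameters
    ----------
    model_type:
        ``"wiener"`` (2 parameter slots) or ``"ou"`` (4 slots).
    random_effects:
        Per-slot flag; ``True`` means the parameter is drawn per individual
        from a population normal, ``False`` means one value is shared by the
        whole cohort (a fixed effect).
    """

    model_type: str
    random_effects: tuple[bool, ...]

    def __post_init__(self) -> None:
        if self.model_type not in ("wiener", "ou"):
            raise ValueError(f"unknown model_type {self.model_type!r}")
        expected = 2 if self.model_type == "wiener" else 4
        if len(self.random_effects) != expected:
            raise ValueError(
                f"{self.model_type} model has {expected} parameter slots, "
                f"got {len(self.random_effects)} random-effect flags"
            )

    @classmethod
    def from_variant(cls, variant_id: int) -> "ModelSpec":
        try:
            model_type, flags = _VARIANTS[variant_id]
        except KeyError:
            raise ValueError(f"variant_id must be 1..4, got {variant_id}")
        return cls(model_type, flags)

    @property
    def variant_id(self) -> int:
        for vid, (mt, flags) in _VARIANTS.items():
            if mt == self.model_type and flags == self.random_effects:
                return vid
        raise ValueError("spec does not correspond to a catalogued variant")

    @property
    def n_slots(self) -> int:
        return len(self.random_effects)

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ("phi1", "phi2", "phi3", "phi4")
        return names[: self.n_slots]

    @property
    def random_mask(self) -> np.ndarray:
        return np.asarray(self.random_effects, dtype=bool)


@dataclass(frozen=True)
class IndividualParams:
    """Per-individual parameter vector phi.

    phi1: latent initial state (the transformed baseline observation).
    phi2: log diffusion SD per sqrt(day); unbounded, higher means a more
        variable trajectory.
    phi3: log mean-reversion rate per day (OU only).
    phi4: long-term latent constant the OU state reverts towards (OU only).
    """

    phi1: float
    phi2: float
    phi3: float | None = None
    phi4: float | None = None

    def as_array(self, spec: ModelSpec) -> np.ndarray:
        vals = [self.phi1, self.phi2]
        if spec.model_type == "ou":
            if self.phi3 is None or self.phi4 is None:
                raise ValueError("phi3 and phi4 are required for the OU model")
            vals += [self.phi3, self.phi4]
        out = np.asarray(vals, dtype=float)
        if not np.all(np.isfinite(out)):
            raise ValueError(f"non-finite individual parameters: {out}")
        return out

    @classmethod
    def from_array(cls, phi: np.ndarray, spec: ModelSpec) -> "IndividualParams":
        phi = np.asarray(phi, dtype=float)
        if spec.model_type == "ou":
            return cls(phi[0], phi[1], phi[2], phi[3])
        return cls(phi[0], phi[1])


def _check_dt(dt: float) -> float:
    dt = float(dt)
    if not np.isfinite(dt) or dt < 0:
        raise ValueError(f"elapsed time must be a non-negative number, got {dt}")
    return dt


def wiener_transition(x0, dt: float, phi2: float) -> GaussianMoments:
    """Conditional law of the Wiener state after ``dt`` days from ``x0``.

    mean = x0, variance = exp(2*phi2) * dt.  Vectorised over ``x0``.
    """
    dt = _check_dt(dt)
    x0 = np.asarray(x0, dtype=float)
    var = np.exp(2.0 * phi2) * dt
    return GaussianMoments(mean=x0 + 0.0, variance=np.broadcast_to(var, x0.shape).copy() if x0.ndim else var)


def ou_transition(x0, dt: float, phi2: float, phi3: float, phi4: float) -> GaussianMoments:
    """Conditional law of the OU state after ``dt`` days from ``x0``.

    With rate theta = exp(phi3) and diffusion variance sigma2 = exp(2*phi2):

        mean     = phi4 + (x0 - phi4) * exp(-theta*dt)
        variance = sigma2 / (2*theta) * (1 - exp(-2*theta*dt))

    The variance uses expm1 so the small-rate limit reproduces the Wiener
    variance ``sigma2 * dt`` to full precision.
    """
    dt = _check_dt(dt)
    x0 = np.asarray(x0, dtype=float)
    theta = np.exp(phi3)
    sigma2 = np.exp(2.0 * phi2)
    decay = np.exp(-theta * dt)
    mean = phi4 + (x0 - phi4) * decay
    # -expm1(-2 theta dt) / (2 theta) -> dt as theta -> 0
    var = sigma2 * (-np.expm1(-2.0 * theta * dt)) / (2.0 * theta)
    if x0.ndim:
        var = np.broadcast_to(var, x0.shape).copy()
    return GaussianMoments(mean=mean, variance=var)


def transition(x0, dt: float, phi: np.ndarray, spec: ModelSpec) -> GaussianMoments:
    """Dispatch to the exact transition for ``spec`` given a phi vector."""
    if spec.model_type == "wiener":
        return wiener_transition(x0, dt, phi[1])
    return ou_transition(x0, dt, phi[1], phi[2], phi[3])


def simulate_latent_path(
    params: IndividualParams | np.ndarray,
    spec: ModelSpec,
    times: np.ndarray,
    noise: np.ndarray,
) -> np.ndarray:
    """Simulate the latent state at ``times`` exactly, driven by ``noise``.

    The path starts at x(0) = phi1.  One standard-normal deviate is consumed
    per transition; a leading time of exactly 0 needs no deviate (the state
    there is phi1 itself), so ``len(noise)`` must equal the number of
    positive gaps.  Deterministic given (params, times, noise).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if times[0] < 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing and start at >= 0")
    phi = params.as_array(spec) if isinstance(params, IndividualParams) else np.asarray(params, float)
    noise = np.asarray(noise, dtype=float)

    full_times = times if times[0] == 0.0 else np.concatenate(([0.0], times))
    n_steps = full_times.size - 1
    if noise.shape != (n_steps,):
        raise ValueError(f"noise must have length {n_steps}, got {noise.shape}")

    states = np.empty(full_times.size)
    states[0] = phi[0]
    for i in range(n_steps):
        dt = full_times[i + 1] - full_times[i]
        mom = transition(states[i], dt, phi, spec)
        states[i + 1] = mom.mean + np.sqrt(mom.variance) * noise[i]
    return states if times[0] == 0.0 else states[1:]
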