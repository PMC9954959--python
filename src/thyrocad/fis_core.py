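"""First-order Takagi–Sugeno fuzzy inference core.

The classifier is an adaptive neuro-fuzzy inference system (ANFIS): a rule
base in which every rule owns one Gaussian membership function per input
dimension (the *premise*) and a linear function of the inputs (the
*consequent*).  For an input vector ``x`` the model output is

    y(x) = sum_i  wbar_i(x) * (p_i . x + r_i)

where ``wbar_i`` is the normalized firing strength of rule ``i`` — the
product of its membership values divided by the sum of those products over
all rules.  The continuous output is thresholded at 0.5 to call a nodule
benign (target 0) or malignant (target 1).

Rule firing is evaluated in log-space and shifted before exponentiation, so
normalization never divides by zero even far from every rule center.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SIGMA_FLOOR",
    "GaussianMF",
    "SugenoRule",
    "AnfisModel",
    "ParameterVector",
    "membership",
    "firing_strengths",
    "forward",
    "forward_batch",
    "classify",
    "parameter_count",
    "encode",
    "decode",
    "fit_scaling",
    "apply_scaling",
    "save_model",
    "load_model",
]

#: Lower bound on Gaussian spreads, on the scaled [0, 1] input axis.  Keeps
#: memberships non-degenerate and firing-strength gradients finite.
SIGMA_FLOOR = 1e-3


@dataclass(frozen=True)
class GaussianMF:
    """Gaussian membership function with center ``c`` and spread ``sigma``."""

    center: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class SugenoRule:
    """One fuzzy rule: per-input Gaussian premises and a linear consequent."""

    premises: tuple[GaussianMF, ...]
    consequent_coeffs: tuple[float, ...]
    consequent_bias: float

    def __post_init__(self) -> None:
        if len(self.premises) != len(self.consequent_coeffs):
            raise ValueError(
                "premise and consequent dimensions disagree: "
                f"{len(self.premises)} vs {len(self.consequent_coeffs)}"
            )

    @property
    def n_inputs(self) -> int:
        return len(self.premises)


@dataclass(frozen=True)
class AnfisModel:
    """A complete Sugeno rule base plus the per-dimension input scaling.

    ``input_scaling`` stores the training-set (min, max) of each raw input
    dimension; raw feature codes are min–max mapped to [0, 1] before any
    membership evaluation so that Gaussian spreads are commensurate across
    signs.  The scaling is part of the model: test data reuse the training
    map.
    """

    rules: tuple[SugenoRule, ...]
    input_scaling: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.rules) < 1:
            raise ValueError("model needs at least one rule")
        n = self.rules[0].n_inputs
        if any(r.n_inputs != n for r in self.rules):
            raise ValueError("all rules must share the input dimension")
        if len(self.input_scaling) != n:
            raise ValueError("input_scaling length must equal n_inputs")

    @property
    def n_inputs(self) -> int:
        return self.rules[0].n_inputs

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    # convenience array views -------------------------------------------------

    def centers(self) -> np.ndarray:
        """(n_rules, n_inputs) premise centers."""
        return np.array([[mf.center for mf in r.premises] for r in self.rules])

    def sigmas(self) -> np.ndarray:
        """(n_rules, n_inputs) premise spreads."""
        return np.array([[mf.sigma for mf in r.premises] for r in self.rules])

    def coeffs(self) -> np.ndarray:
        """(n_rules, n_inputs) consequent slopes."""
        return np.array([r.consequent_coeffs for r in self.rules])

    def biases(self) -> np.ndarray:
        """(n_rules,) consequent intercepts."""
        return np.array([r.consequent_bias for r in self.rules])


@dataclass(frozen=True)
class ParameterVector:
    """Flat encoding of every free parameter — the GA chromosome.

    Layout: all premise (center, sigma) pairs, rule-major then input-major,
    followed by all consequent blocks ``(p_1..p_n, r)``, rule-major.
    """

    values: np.ndarray
    n_inputs: int
    n_rules: int

    def __post_init__(self) -> None:
        expect = parameter_count(self.n_inputs, self.n_rules)
        if self.values.shape != (expect,):
            raise ValueError(
                f"parameter vector has shape {self.values.shape}, "
                f"expected ({expect},) for {self.n_rules} rules on "
                f"{self.n_inputs} inputs"
            )


def parameter_count(n_inputs: int, n_rules: int) -> int:
    """Number of free parameters of a model with one Gaussian MF per input
    per rule and first-order consequents.

    Premises contribute ``2 * n_inputs`` per rule (center and spread),
    consequents ``n_inputs + 1`` per rule (slopes and intercept).
    """
    if n_inputs < 1 or n_rules < 1:
        raise ValueError("n_inputs and n_rules must be positive")
    return n_rules * (2 * n_inputs) + n_rules * (n_inputs + 1)


def membership(mf: GaussianMF, x: float) -> float:
    """Gaussian membership exp(-(x - c)^2 / (2 sigma^2)), in (0, 1]."""
    if not mf.sigma > 0:
        raise ValueError(f"sigma must be positive, got {mf.sigma}")
    z = (x - mf.center) / mf.sigma
    return float(np.exp(-0.5 * z * z))


def _log_firing(model: AnfisModel, X: np.ndarray) -> np.ndarray:
    """(n_samples, n_rules) log raw firing strengths."""
    c = model.centers()[None, :, :]          # (1, R, n)
    s = model.sigmas()[None, :, :]
    z = (X[:, None, :] - c) / s              # (N, R, n)
    return -0.5 * np.sum(z * z, axis=2)


def _normalize_log(logw: np.ndarray) -> np.ndarray:
    """Shift log strengths and exponentiate; rows sum to one exactly."""
    shifted = logw - logw.max(axis=1, keepdims=True)
    w = np.exp(shifted)
    return w / w.sum(axis=1, keepdims=True)


def firing_strengths(model: AnfisModel, x: np.ndarray) -> np.ndarray:
    """Normalized firing strengths wbar for a single (scaled) input vector."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_inputs,):
        raise ValueError(f"expected input of shape ({model.n_inputs},), got {x.shape}")
    return _normalize_log(_log_firing(model, x[None, :]))[0]


def forward(model: AnfisModel, X: np.ndarray) -> np.ndarray:
    """Continuous model output for scaled inputs.

    Accepts a single vector (returns a scalar array of shape ()) or a
    (n_samples, n_inputs) matrix (returns (n_samples,)).
    """
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != model.n_inputs:
        raise ValueError(f"expected {model.n_inputs} inputs, got {X.shape[1]}")
    wbar = _normalize_log(_log_firing(model, X))           # (N, R)
    f = X @ model.coeffs().T + model.biases()[None, :]     # (N, R)
    y = np.sum(wbar * f, axis=1)
    return y[0] if single else y


def classify(model: AnfisModel, X: np.ndarray) -> np.ndarray:
    """Threshold the continuous output at 0.5; ties go to malignant (1)."""
    return (np.atleast_1d(forward(model, X)) >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# flat encoding / decoding


def encode(model: AnfisModel) -> ParameterVector:
    """Flatten a model into its chromosome representation."""
    premise = np.stack([model.centers(), model.sigmas()], axis=2).ravel()
    consequent = np.concatenate(
        [model.coeffs(), model.biases()[:, None]], axis=1
    ).ravel()
    return ParameterVector(
        values=np.concatenate([premise, consequent]),
        n_inputs=model.n_inputs,
        n_rules=model.n_rules,
    )


def decode(
    values: np.ndarray,
    n_inputs: int,
    n_rules: int,
    input_scaling: tuple[tuple[float, float], ...],
) -> AnfisModel:
    """Rebuild a model from a flat vector, clamping spreads to SIGMA_FLOOR."""
    values = np.asarray(values, dtype=float)
    expect = parameter_count(n_inputs, n_rules)
    if values.shape != (expect,):
        raise ValueError(
            f"vector of length {values.size} cannot decode into "
            f"({n_inputs} inputs, {n_rules} rules): need {expect}"
        )
    n_premise = 2 * n_inputs * n_rules
    prem = values[:n_premise].reshape(n_rules, n_inputs, 2)
    cons = values[n_premise:].reshape(n_rules, n_inputs + 1)
    rules = tuple(
        SugenoRule(
            premises=tuple(
                GaussianMF(center=float(c), sigma=float(max(s, SIGMA_FLOOR)))
                for c, s in prem[i]
            ),
            consequent_coeffs=tuple(float(v) for v in cons[i, :n_inputs]),
            consequent_bias=float(cons[i, n_inputs]),
        )
        for i in range(n_rules)
    )
    return AnfisModel(rules=rules, input_scaling=tuple(input_scaling))


def split_params(values: np.ndarray, n_inputs: int, n_rules: int):
    """View a flat vector as (centers, sigmas, coeffs, biases) arrays."""
    n_premise = 2 * n_inputs * n_rules
    prem = values[:n_premise].reshape(n_rules, n_inputs, 2)
    cons = values[n_premise:].reshape(n_rules, n_inputs + 1)
    return prem[:, :, 0], prem[:, :, 1], cons[:, :n_inputs], cons[:, n_inputs]


def forward_batch(
    population: np.ndarray, n_inputs: int, n_rules: int, X: np.ndarray
) -> np.ndarray:
    """Evaluate many parameter vectors at once.

    ``population`` is (n_chromosomes, n_params); returns the continuous
    outputs as (n_chromosomes, n_samples).  Spreads are clamped exactly as
    :func:`decode` would clamp them, so batched fitness matches the decoded
    models.  Used by the population-based trainer, where evaluating the
    whole generation in one broadcast pass dominates the run time.
    """
    population = np.atleast_2d(np.asarray(population, dtype=float))
    n_premise = 2 * n_inputs * n_rules
    prem = population[:, :n_premise].reshape(-1, n_rules, n_inputs, 2)
    cons = population[:, n_premise:].reshape(-1, n_rules, n_inputs + 1)
    c = prem[:, :, :, 0]                                   # (P, R, n)
    s = np.maximum(prem[:, :, :, 1], SIGMA_FLOOR)
    z = (X[None, :, None, :] - c[:, None, :, :]) / s[:, None, :, :]
    logw = -0.5 * np.sum(z * z, axis=3)                    # (P, N, R)
    wbar = np.exp(logw - logw.max(axis=2, keepdims=True))
    wbar /= wbar.sum(axis=2, keepdims=True)
    f = np.einsum("nj,prj->pnr", X, cons[:, :, :n_inputs]) + cons[:, None, :, n_inputs]
    return np.sum(wbar * f, axis=2)                        # (P, N)


# ---------------------------------------------------------------------------
# raw-code scaling


def fit_scaling(X_raw: np.ndarray) -> tuple[tuple[float, float], ...]:
    """Per-dimension (min, max) of the training inputs.

    A constant column gets the degenerate pair (v, v); `apply_scaling` maps
    it to 0.5.
    """
    X_raw = np.asarray(X_raw, dtype=float)
    return tuple((float(lo), float(hi)) for lo, hi in zip(X_raw.min(0), X_raw.max(0)))


def apply_scaling(
    scaling: tuple[tuple[float, float], ...], X_raw: np.ndarray
) -> np.ndarray:
    """Min–max map raw codes onto [0, 1] using stored training extrema.

    Out-of-range test values extrapolate linearly (they are not clipped),
    keeping the map affine and invertible per dimension.
    """
    X_raw = np.atleast_2d(np.asarray(X_raw, dtype=float))
    lo = np.array([p[0] for p in scaling])
    hi = np.array([p[1] for p in scaling])
    span = hi - lo
    out = np.empty_like(X_raw)
    flat = span == 0
    out[:, ~flat] = (X_raw[:, ~flat] - lo[~flat]) / span[~flat]
    out[:, flat] = 0.5
    return out


# ---------------------------------------------------------------------------
# serialization


def save_model(model: AnfisModel, path) -> None:
    """Write a model as a flat JSON document with a bit-exact round trip.

    Parameter values are stored as hex floats so that load(save(m)) == m to
    the last bit.
    """
    vec = encode(model)
    doc = {
        "format": "thyrocad-anfis-1",
        "n_inputs": model.n_inputs,
        "n_rules": model.n_rules,
        "layout": "premise(c,sigma) rule-major input-major; consequent(p...,r) rule-major",
        "input_scaling": [[lo.hex(), hi.hex()] for lo, hi in
                          ((float(a), float(b)) for a, b in model.input_scaling)],
        "values": [float(v).hex() for v in vec.values],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path) -> AnfisModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "thyrocad-anfis-1":
        raise ValueError(f"not a thyrocad model file: {path}")
    scaling = tuple(
        (float.fromhex(lo), float.fromhex(hi)) for lo, hi in doc["input_scaling"]
    )
    values = np.array([float.fromhex(v) for v in doc["values"]])
    return decode(values, doc["n_inputs"], doc["n_rules"], scaling)
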