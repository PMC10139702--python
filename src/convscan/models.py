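"""Reversible 20-state amino-acid substitution models.

A model is the usual general-time-reversible construction: a symmetric
exchangeability matrix ``S`` and equilibrium frequencies ``pi`` combine
into the rate matrix ``Q_ij = S_ij * pi_j`` (i != j), with the diagonal set
so rows sum to zero and the whole matrix scaled so that
``-sum_i pi_i * Q_ii = 1`` — branch lengths are then expected substitutions
per site. Transition probabilities ``P(t) = expm(Q t)`` are computed through
the symmetric similarity transform ``B = D^{1/2} Q D^{-1/2}`` (``D =
diag(pi)``), whose eigendecomposition is real and numerically stable.

Empirical matrices (JTT, WAG, LG) ship as plain-text files in the classic
PAML ``.dat`` layout: 19 lower-triangular exchangeability rows, a blank
line, then 20 equilibrium frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .alphabet import N_STATES

__all__ = [
    "ModelError",
    "SubstitutionModel",
    "TransitionMatrix",
    "build_rate_matrix",
    "transition_matrix",
    "equal_rates_model",
    "load_empirical_model",
    "EMPIRICAL_MODELS",
]

#: Names of the shipped empirical exchangeability matrices.
EMPIRICAL_MODELS = ("JTT", "WAG", "LG")

_FREQ_TOL = 1e-6


class ModelError(ValueError):
    """A substitution model could not be constructed from its inputs."""


@dataclass(frozen=True)
class SubstitutionModel:
    """A normalized reversible amino-acid substitution process.

    Attributes
    ----------
    name : str
        Identifier such as ``"JTT"`` or ``"EQ"``.
    exchangeabilities : (20, 20) ndarray
        Symmetric nonnegative matrix with zero diagonal.
    frequencies : (20,) ndarray
        Equilibrium distribution pi (strictly positive, sums to 1).
    rate_matrix : (20, 20) ndarray
        Normalized generator Q.
    """

    name: str
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    rate_matrix: np.ndarray
    # eigendecomposition of the pi-symmetrized generator, cached for P(t)
    _eigvals: np.ndarray = field(repr=False, default=None)
    _right: np.ndarray = field(repr=False, default=None)  # D^{-1/2} V
    _left: np.ndarray = field(repr=False, default=None)  # V^T D^{1/2}

    def transition_probs(self, t: float) -> np.ndarray:
        """Row-stochastic transition matrix ``P(t) = expm(Q t)``."""
        if t < 0:
            raise ModelError(f"branch length must be nonnegative, got {t}")
        if t == 0:  # exact: a zero-length branch forbids change exactly
            return np.eye(N_STATES)
        P = (self._right * np.exp(self._eigvals * t)) @ self._left
        # eigendecomposition round-off only; genuine defects must surface
        err = np.abs(P.sum(axis=1) - 1.0).max()
        if err > 1e-8:
            raise ModelError(
                f"transition matrix rows deviate from 1 by {err:.3e}; "
                "model eigendecomposition is unreliable"
            )
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


@dataclass(frozen=True)
class TransitionMatrix:
    """Transition probabilities over one branch."""

    branch_length: float
    probs: np.ndarray


def build_rate_matrix(
    exchangeabilities: np.ndarray,
    frequencies: np.ndarray,
    name: str = "custom",
) -> SubstitutionModel:
    """Assemble and normalize a reversible rate matrix.

    Raises
    ------
    ModelError
        Distinct messages for non-symmetric or negative exchangeabilities,
        a nonzero diagonal, invalid frequencies, or an all-zero process.
    """
    S = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(frequencies, dtype=float)
    if S.shape != (N_STATES, N_STATES):
        raise ModelError(f"exchangeabilities must be 20x20, got {S.shape}")
    if not np.allclose(S, S.T, atol=1e-12, rtol=1e-9):
        raise ModelError("exchangeability matrix is not symmetric")
    if (S < 0).any():
        raise ModelError("exchangeabilities contain negative entries")
    if np.abs(np.diag(S)).max() > 0:
        raise ModelError("exchangeability diagonal must be zero")
    if pi.shape != (N_STATES,):
        raise ModelError(f"frequencies must have length 20, got {pi.shape}")
    if (pi <= 0).any():
        raise ModelError("equilibrium frequencies must all be strictly positive")
    if abs(pi.sum() - 1.0) > _FREQ_TOL:
        raise ModelError(f"frequencies sum to {pi.sum():.8f}, not 1")
    pi = pi / pi.sum()

    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    rate = float(pi @ Q.sum(axis=1))
    if rate <= 0:
        raise ModelError("all exchangeabilities are zero: no substitution process")
    Q /= rate
    np.fill_diagonal(Q, -Q.sum(axis=1))

    sqrt_pi = np.sqrt(pi)
    B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
    B = 0.5 * (B + B.T)  # symmetric up to round-off by reversibility
    eigvals, V = np.linalg.eigh(B)
    right = V / sqrt_pi[:, None]
    left = V.T * sqrt_pi[None, :]

    return SubstitutionModel(
        name=name,
        exchangeabilities=S,
        frequencies=pi,
        rate_matrix=Q,
        _eigvals=eigvals,
        _right=right,
        _left=left,
    )


def transition_matrix(model: SubstitutionModel, t: float) -> TransitionMatrix:
    """Transition probabilities for a branch of length ``t``."""
    return TransitionMatrix(branch_length=float(t), probs=model.transition_probs(t))


def equal_rates_model() -> SubstitutionModel:
    """The 20-state equal-rates (Jukes–Cantor-type) model."""
    S = np.ones((N_STATES, N_STATES))
    np.fill_diagonal(S, 0.0)
    pi = np.full(N_STATES, 1.0 / N_STATES)
    return build_rate_matrix(S, pi, name="EQ")


def _parse_paml_dat(text: str, source: str) -> tuple[np.ndarray, np.ndarray]:
    values: list[float] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        for tok in line.split():
            try:
                values.append(float(tok))
            except ValueError:
                raise ModelError(
                    f"{source}:{lineno}: non-numeric token {tok!r}"
                ) from None
    if len(values) < 210:
        raise ModelError(
            f"{source}: expected 190 exchangeabilities + 20 frequencies, "
            f"found {len(values)} numbers"
        )
    S = np.zeros((N_STATES, N_STATES))
    k = 0
    for i in range(1, N_STATES):
        for j in range(i):
            S[i, j] = S[j, i] = values[k]
            k += 1
    pi = np.array(values[k : k + N_STATES])
    return S, pi


def load_empirical_model(
    name: str,
    frequencies: np.ndarray | None = None,
    path: str | Path | None = None,
) -> SubstitutionModel:
    """Load a shipped empirical model, or any PAML-layout ``.dat`` file.

    Parameters
    ----------
    name : str
        ``"JTT"``, ``"WAG"``, ``"LG"`` (shipped), ``"EQ"`` (equal rates),
        or a label for a custom ``path``.
    frequencies : optional
        Replacement equilibrium frequencies (the ``+F`` option: observed
        alignment frequencies). Defaults to the file's own frequencies.
    path : optional
        Explicit ``.dat`` file overriding the shipped data.
    """
    key = name.upper()
    if path is None and key == "EQ":
        model = equal_rates_model()
        if frequencies is None:
            return model
        return build_rate_matrix(model.exchangeabilities, frequencies, name="EQ+F")
    if path is not None:
        text = Path(path).read_text()
        source = str(path)
    elif key in EMPIRICAL_MODELS:
        source = f"{key.lower()}.dat"
        text = (resources.files("convscan.data") / source).read_text()
    else:
        raise ModelError(
            f"unknown model {name!r}: expected one of "
            f"{EMPIRICAL_MODELS + ('EQ',)} or an explicit path"
        )
    S, file_pi = _parse_paml_dat(text, source)
    pi = file_pi if frequencies is None else np.asarray(frequencies, dtype=float)
    label = key if frequencies is None else f"{key}+F"
    return build_rate_matrix(S, pi, name=label)


def observed_frequencies(counts: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Normalize residue counts into strictly positive frequencies.

    Zero counts are floored at ``floor`` so the resulting process remains
    irreducible (a residue absent from one ortholog is not impossible).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (N_STATES,) or (counts < 0).any():
        raise ModelError("counts must be a length-20 nonnegative vector")
    if counts.sum() == 0:
        raise ModelError("cannot derive frequencies from an empty alignment")
    pi = counts / counts.sum()
    pi = np.maximum(pi, floor)
    return pi / pi.sum()
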