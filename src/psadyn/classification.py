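"""Patient typing from the fitted on/off rate matrices.

A fitted parameter set is sorted into one of three clinically meaningful
types by spectral analysis of the two continuous-time rate matrices
``W1`` (on-treatment) and ``W0`` (off-treatment):

* **type (i)** — some convex combination ``a*W1 + (1-a)*W0`` with
  ``a in (0, 1)`` has all eigenvalues with negative real part.  An
  intermittent schedule spending roughly that fraction of time on therapy
  can then drive the tumor burden down indefinitely: relapse is preventable
  by intermittent suppression.
* **type (ii)** — not type (i), but at least one compartment grows strictly
  slower off treatment than on it (``w1_ii > w0_ii`` for some i).  Relapse
  cannot be prevented, but inserting off-periods delays it relative to
  continuous suppression.
* **type (iii)** — neither: continuous suppression is the better long-run
  strategy.

The combination is generally non-symmetric, so "negative eigenvalues" is
read as negative real parts.  The search over ``a`` uses a fixed fine grid;
the spectral abscissa is continuous along the convex path, so a grid is
adequate and keeps the procedure reproducible.

Each bootstrap member is classified independently of the data it was fitted
to, and a patient's label is the most frequent type across the ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Optional, Sequence, Tuple

import numpy as np

from .tumor_model import RateMatrices, to_continuous

__all__ = [
    "PatientType",
    "ClassificationConfig",
    "spectral_abscissa",
    "is_type_i",
    "suppressive_alpha",
    "classify",
    "classify_ensemble",
    "most_frequent_type",
]


class PatientType(IntEnum):
    """Three-way partition of parameter space; higher numbers are less favorable."""

    TYPE_I = 1
    TYPE_II = 2
    TYPE_III = 3

    @property
    def label(self) -> str:
        return {1: "type-i", 2: "type-ii", 3: "type-iii"}[self.value]


@dataclass(frozen=True)
class ClassificationConfig:
    """Grid over the mixing parameter and the eigenvalue-negativity tolerance.

    The default grid has 999 evenly spaced points strictly inside (0, 1)
    (step 0.001).  ``tol`` = 0 means strictly negative real parts.
    """

    n_alpha: int = 999
    tol: float = 0.0

    def alphas(self) -> np.ndarray:
        n = self.n_alpha
        if n < 1:
            raise ValueError("need at least one grid point")
        return np.arange(1, n + 1) / (n + 1)


def _combination_stack(w: RateMatrices, alphas: np.ndarray) -> np.ndarray:
    w1 = w.on_matrix()
    w0 = w.off_matrix()
    a = alphas[:, None, None]
    return a * w1 + (1.0 - a) * w0


def spectral_abscissa(w: RateMatrices, alphas: np.ndarray) -> np.ndarray:
    """Max real part of the eigenvalues of ``a*W1 + (1-a)*W0`` for each grid a.

    Every convex combination inherits the model's sparsity: its third
    column vanishes except on the diagonal, so the spectrum is exactly the
    combined irreversible-compartment rate plus the two eigenvalues of the
    top-left 2x2 block.  Those are evaluated in closed form (vectorized
    over the grid), which is exact and much faster than a dense
    eigensolve; :func:`_spectral_abscissa_dense` keeps the generic path for
    cross-checking.
    """
    a = np.asarray(alphas, dtype=float)
    c11 = a * w.w1_11 + (1 - a) * w.w0_11
    c12 = (1 - a) * w.w0_12
    c21 = a * w.w1_21
    c22 = a * w.w1_22 + (1 - a) * w.w0_22
    c33 = a * w.w1_33 + (1 - a) * w.w0_33
    half_trace = 0.5 * (c11 + c22)
    disc = (0.5 * (c11 - c22)) ** 2 + c12 * c21
    block_max = np.where(disc >= 0, half_trace + np.sqrt(np.maximum(disc, 0.0)), half_trace)
    return np.maximum(block_max, c33)


def _spectral_abscissa_dense(w: RateMatrices, alphas: np.ndarray) -> np.ndarray:
    """Generic eigensolver version of :func:`spectral_abscissa` (reference path)."""
    stack = _combination_stack(w, np.asarray(alphas, dtype=float))
    eig = np.linalg.eigvals(stack)
    return eig.real.max(axis=1)


def is_type_i(
    w: RateMatrices, config: Optional[ClassificationConfig] = None
) -> Tuple[bool, Optional[float]]:
    """Whether some grid mixture of the on/off rates is uniformly decaying.

    Returns ``(True, witness)`` with the first grid value whose combination
    has all eigenvalue real parts below ``-tol``, else ``(False, None)``.
    """
    config = config or ClassificationConfig()
    alphas = config.alphas()
    abscissa = spectral_abscissa(w, alphas)
    hits = np.flatnonzero(abscissa < -config.tol)
    if hits.size == 0:
        return False, None
    return True, float(alphas[hits[0]])


def suppressive_alpha(
    w: RateMatrices, config: Optional[ClassificationConfig] = None
) -> Tuple[float, float]:
    """Grid mixture minimising the spectral abscissa, with its abscissa value.

    For a type-(i) parameter set this is the most robustly suppressive
    on-treatment fraction: a duty-cycle schedule spending about this
    fraction of time on therapy contracts the tumor burden fastest among
    grid mixtures.
    """
    config = config or ClassificationConfig()
    alphas = config.alphas()
    abscissa = spectral_abscissa(w, alphas)
    k = int(np.argmin(abscissa))
    return float(alphas[k]), float(abscissa[k])


def classify(
    w: RateMatrices, config: Optional[ClassificationConfig] = None
) -> PatientType:
    """Assign type (i)/(ii)/(iii); the type-(ii) test runs only if type (i) fails."""
    config = config or ClassificationConfig()
    ok, _ = is_type_i(w, config)
    if ok:
        return PatientType.TYPE_I
    if w.w1_11 > w.w0_11 or w.w1_22 > w.w0_22 or w.w1_33 > w.w0_33:
        return PatientType.TYPE_II
    return PatientType.TYPE_III


def classify_ensemble(ensemble, config: Optional[ClassificationConfig] = None):
    """Classify every bootstrap member and store the labels on the ensemble."""
    config = config or ClassificationConfig()
    labels = tuple(classify(to_continuous(m.d), config) for m in ensemble.members)
    ensemble.types = labels
    return labels


def most_frequent_type(
    ensemble, config: Optional[ClassificationConfig] = None
) -> Tuple[PatientType, dict]:
    """Modal type across the ensemble with the full count vector.

    Ties break toward the higher-numbered (clinically less favorable) type.
    Accepts a :class:`~psadyn.psa_fitting.BootstrapEnsemble` (classifying
    members on demand) or any sequence of :class:`PatientType` labels.
    """
    if isinstance(ensemble, (list, tuple)):
        labels: Sequence[PatientType] = tuple(PatientType(t) for t in ensemble)
    else:
        labels = ensemble.types or classify_ensemble(ensemble, config)
    if len(labels) == 0:
        raise ValueError("cannot take the modal type of an empty ensemble")
    counts = {t: 0 for t in PatientType}
    for t in labels:
        counts[PatientType(t)] += 1
    best = max(counts.values())
    modal = max(t for t, c in counts.items() if c == best)
    return modal, {t.label: c for t, c in counts.items()}
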