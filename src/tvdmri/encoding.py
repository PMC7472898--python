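"""Diffusion-encoding b-tensors and acquisition protocols.

Tensor-valued diffusion encoding summarises each acquired volume by a 3x3
symmetric b-tensor ``B`` (units s/mm^2).  For a Gaussian compartment with
diffusion tensor ``D`` the signal attenuation is ``exp(-B:D)`` where ``:``
is the Frobenius inner product.  Two tensor shapes are supported:

* linear (LTE): ``B = b * n n^T``, the conventional single-direction
  (Stejskal-Tanner) weighting; rank 1.
* spherical (STE): ``B = (b/3) * I``, isotropic weighting that sensitises
  the measurement equally to all directions; rank 3.

A :class:`Protocol` is an ordered list of encodings plus shell structure
derived from the (b-value, shape) pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np

__all__ = [
    "LINEAR",
    "SPHERICAL",
    "BTensor",
    "Encoding",
    "Protocol",
    "make_lte_btensor",
    "make_ste_btensor",
    "repulsion_directions",
    "tensor_valued_protocol",
    "multishell_protocol",
]

LINEAR = "linear"
SPHERICAL = "spherical"

_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class BTensor:
    """A 3x3 symmetric positive semi-definite b-tensor (s/mm^2)."""

    matrix: np.ndarray
    shape_label: str

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("b-tensor matrix must be 3x3")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("b-tensor matrix must be symmetric")
        object.__setattr__(self, "matrix", m)

    @property
    def b_value(self) -> float:
        """Nominal b-value: the trace of the b-tensor."""
        return float(np.trace(self.matrix))


@dataclass(frozen=True)
class Encoding:
    """One acquired volume: b-value, tensor shape, and LTE direction.

    ``direction`` is None for spherical encodings and for b=0 entries.
    """

    b_value: float
    shape_label: str
    direction: np.ndarray | None = None

    def __post_init__(self):
        if self.b_value < 0:
            raise ValueError("b-value must be non-negative")
        if self.shape_label not in (LINEAR, SPHERICAL):
            raise ValueError(f"unknown shape label {self.shape_label!r}")
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=float)
            if d.shape != (3,):
                raise ValueError("direction must be a 3-vector")
            if abs(np.linalg.norm(d) - 1.0) > _UNIT_TOL:
                raise ValueError("direction must have unit norm")
            object.__setattr__(self, "direction", d)
        if self.direction is None and self.shape_label == LINEAR and self.b_value > 0:
            raise ValueError("linear encoding with b > 0 requires a direction")

    @property
    def btensor(self) -> BTensor:
        if self.shape_label == SPHERICAL:
            return make_ste_btensor(self.b_value)
        if self.b_value == 0:
            return BTensor(np.zeros((3, 3)), LINEAR)
        return make_lte_btensor(self.b_value, self.direction)


def make_lte_btensor(b_value: float, direction) -> BTensor:
    """Linear (rank-1) b-tensor ``b * n n^T`` for unit direction ``n``."""
    if b_value < 0:
        raise ValueError("b-value must be non-negative")
    n = np.asarray(direction, dtype=float)
    if n.shape != (3,):
        raise ValueError("direction must be a 3-vector")
    if abs(np.linalg.norm(n) - 1.0) > _UNIT_TOL:
        raise ValueError("direction must have unit norm")
    return BTensor(b_value * np.outer(n, n), LINEAR)


def make_ste_btensor(b_value: float) -> BTensor:
    """Spherical (isotropic) b-tensor ``(b/3) * I``."""
    if b_value < 0:
        raise ValueError("b-value must be non-negative")
    return BTensor((b_value / 3.0) * np.eye(3), SPHERICAL)


def repulsion_directions(n: int, seed: int, n_iter: int = 2000, step: float = 0.05) -> np.ndarray:
    return _repulsion_directions_cached(int(n), int(seed), int(n_iter), float(step)).copy()


@lru_cache(maxsize=256)
def _repulsion_directions_cached(n: int, seed: int, n_iter: int, step: float) -> np.ndarray:
    """Electrostatically repulsed unit directions, antipodally symmetric.

    Starting from a seeded random configuration, points are iteratively
    pushed apart by a Coulomb-like force acting between every pair of
    points and their antipodes, then renormalised.  Deterministic given
    ``seed``.

    Returns an (n, 3) array of unit vectors.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    if n == 1:
        return x
    for _ in range(n_iter):
        force = np.zeros_like(x)
        for sign in (1.0, -1.0):
            diff = x[:, None, :] - sign * x[None, :, :]  # (n, n, 3)
            dist2 = np.einsum("ijk,ijk->ij", diff, diff)
            np.fill_diagonal(dist2, np.inf)
            if sign < 0:
                # antipodal self-pair has distance 2, keep it
                np.fill_diagonal(dist2, 4.0)
                np.fill_diagonal(diff[..., 0], 2 * x[:, 0])
                np.fill_diagonal(diff[..., 1], 2 * x[:, 1])
                np.fill_diagonal(diff[..., 2], 2 * x[:, 2])
            force += np.einsum("ij,ijk->ik", dist2 ** -1.5, diff)
        x = x + step / n * force
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    # canonical hemisphere: first nonzero component positive
    flip = x[:, 2] < 0
    x[flip] *= -1
    return x


def min_pairwise_angle_deg(directions: np.ndarray) -> float:
    """Smallest pairwise angle (degrees) treating antipodes as identical."""
    d = np.asarray(directions, dtype=float)
    g = np.abs(d @ d.T)
    np.fill_diagonal(g, 0.0)
    return float(np.degrees(np.arccos(np.clip(g.max(), -1, 1))))


@dataclass
class Protocol:
    """Ordered list of encodings with derived shell structure."""

    encodings: list[Encoding]
    name: str = "protocol"

    def __post_init__(self):
        if not self.encodings:
            raise ValueError("protocol must contain at least one encoding")
        # shells keyed by (b, shape); LTE directions within a shell distinct
        for (b, shape), idx in self.shells.items():
            if shape == LINEAR and b > 0:
                dirs = np.array([self.encodings[i].direction for i in idx])
                g = np.abs(dirs @ dirs.T)
                np.fill_diagonal(g, 0.0)
                if np.any(g > 1 - 1e-12):
                    raise ValueError(
                        f"duplicate directions in LTE shell b={b}"
                    )

    def __len__(self) -> int:
        return len(self.encodings)

    @property
    def shells(self) -> dict[tuple[float, str], list[int]]:
        out: dict[tuple[float, str], list[int]] = {}
        for i, e in enumerate(self.encodings):
            out.setdefault((e.b_value, e.shape_label), []).append(i)
        return out

    @property
    def b_values(self) -> np.ndarray:
        return np.array([e.b_value for e in self.encodings])

    @property
    def shape_labels(self) -> list[str]:
        return [e.shape_label for e in self.encodings]

    def btensors(self) -> np.ndarray:
        """All b-tensors stacked as an (n, 3, 3) array."""
        return np.stack([e.btensor.matrix for e in self.encodings])

    # ------------------------------------------------------------------
    # serialization: FSL-style bval/bvec + shape sidecar, or JSON
    # ------------------------------------------------------------------
    def to_fsl(self, prefix: str | Path) -> None:
        """Write ``<prefix>.bval``, ``<prefix>.bvec`` and ``<prefix>.shapes``.

        bvec follows the FSL layout (3 rows); spherical and b=0 entries get
        a zero vector.
        """
        prefix = Path(prefix)
        bvals = self.b_values
        bvecs = np.zeros((3, len(self)))
        for i, e in enumerate(self.encodings):
            if e.direction is not None:
                bvecs[:, i] = e.direction
        np.savetxt(prefix.with_suffix(".bval"), bvals[None, :], fmt="%.6g")
        np.savetxt(prefix.with_suffix(".bvec"), bvecs, fmt="%.12g")
        prefix.with_suffix(".shapes").write_text(
            "\n".join(self.shape_labels) + "\n"
        )

    @classmethod
    def from_fsl(cls, prefix: str | Path, name: str = "protocol") -> "Protocol":
        prefix = Path(prefix)
        bvals = np.atleast_1d(np.loadtxt(prefix.with_suffix(".bval")).ravel())
        bvecs = np.atleast_2d(np.loadtxt(prefix.with_suffix(".bvec")))
        shapes = prefix.with_suffix(".shapes").read_text().split()
        if bvecs.shape != (3, len(bvals)) or len(shapes) != len(bvals):
            raise ValueError("bval/bvec/shapes lengths are inconsistent")
        encs = []
        for i, (b, shape) in enumerate(zip(bvals, shapes)):
            v = bvecs[:, i]
            direction = None
            if shape == LINEAR and b > 0 and np.linalg.norm(v) > 0:
                direction = v / np.linalg.norm(v)
            encs.append(Encoding(float(b), shape, direction))
        return cls(encs, name=name)

    def to_json(self, path: str | Path) -> None:
        """JSON alternative embedding full row-major 3x3 b-tensors."""
        payload = {
            "name": self.name,
            "encodings": [
                {
                    "b_value": e.b_value,
                    "shape": e.shape_label,
                    "btensor": e.btensor.matrix.ravel().tolist(),
                }
                for e in self.encodings
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Protocol":
        payload = json.loads(Path(path).read_text())
        encs = []
        for rec in payload["encodings"]:
            m = np.array(rec["btensor"], dtype=float).reshape(3, 3)
            b = rec["b_value"]
            if rec["shape"] == LINEAR and b > 0:
                # principal axis of the rank-1 tensor
                w, v = np.linalg.eigh(m)
                direction = v[:, np.argmax(w)]
            else:
                direction = None
            encs.append(Encoding(float(b), rec["shape"], direction))
        return cls(encs, name=payload.get("name", "protocol"))


TENSOR_VALUED_BVALUES = (100.0, 500.0, 900.0, 1200.0, 1600.0, 2000.0)
MULTISHELL_BVALUES = (300.0, 1000.0, 2000.0)
MULTISHELL_NDIRS = (6, 50, 50)


def tensor_valued_protocol(
    n_lte_dirs: int = 15, n_ste_reps: int = 15, seed: int = 0
) -> Protocol:
    """The tensor-valued (LTE + STE) acquisition.

    Six b-value shells at 100/500/900/1200/1600/2000 s/mm^2.  Each shell
    carries ``n_lte_dirs`` electrostatically repulsed LTE directions and
    ``n_ste_reps`` spherical-encoding repetitions; 180 encodings at the
    defaults.  Deterministic given ``seed``.
    """
    if n_lte_dirs < 1 or n_ste_reps < 1:
        raise ValueError("direction and repetition counts must be >= 1")
    encs: list[Encoding] = []
    for k, b in enumerate(TENSOR_VALUED_BVALUES):
        dirs = repulsion_directions(n_lte_dirs, seed=seed * 101 + k)
        for d in dirs:
            encs.append(Encoding(b, LINEAR, d))
    for b in TENSOR_VALUED_BVALUES:
        for _ in range(n_ste_reps):
            encs.append(Encoding(b, SPHERICAL))
    return Protocol(encs, name="tensor_valued")


def multishell_protocol(seed: int = 0) -> Protocol:
    """The multi-shell LTE acquisition used for DTI.

    Shells of 6/50/50 directions at b = 300/1000/2000 s/mm^2 plus three
    b=0 volumes; 109 encodings in total.
    """
    encs: list[Encoding] = [Encoding(0.0, LINEAR) for _ in range(3)]
    for k, (b, n) in enumerate(zip(MULTISHELL_BVALUES, MULTISHELL_NDIRS)):
        dirs = repulsion_directions(n, seed=seed * 211 + 7 * k + 1)
        for d in dirs:
            encs.append(Encoding(b, LINEAR, d))
    return Protocol(encs, name="multishell")
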