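"""Diffusion-tensor fitting and fractional anisotropy (FA).

The diffusion tensor model for LTE data is ``S = s0 exp(-B:D)``; taking
logs gives a linear model in (log s0, D) solved per voxel by weighted
linear least squares with weights equal to the squared signal (the
standard variance-stabilising choice for log-transformed Rician data).
Only the b=0 and working-shell (default b=1000 s/mm^2) volumes enter the
fit; other shells in the protocol are ignored.

FA is computed from the tensor eigenvalues:

    FA = sqrt(3/2) * sqrt(sum (l_i - l_mean)^2 / sum l_i^2)

which is 0 for an isotropic tensor and 1 for a stick (one nonzero
eigenvalue).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import LINEAR, Protocol
from .phantom import SignalVolume

__all__ = [
    "DiffusionTensorModel",
    "DiffusionTensorResults",
    "fit_dti",
    "fa_from_eigenvalues",
    "ScalarMap",
]

# D is encoded as the 6-vector (xx, yy, zz, xy, xz, yz); off-diagonals
# appear twice in B:D so their design columns carry a factor 2.
_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
_W = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])


def _design_matrix(btensors: np.ndarray) -> np.ndarray:
    """Rows [1, -B_xx, -B_yy, -B_zz, -2B_xy, -2B_xz, -2B_yz] for log-linear fit."""
    cols = np.stack([btensors[:, i, j] for i, j in _IDX], axis=1) * _W
    return np.hstack([np.ones((len(btensors), 1)), -cols])


def _vec_to_tensor(v: np.ndarray) -> np.ndarray:
    d = np.zeros((3, 3))
    for k, (i, j) in enumerate(_IDX):
        d[i, j] = v[k]
        d[j, i] = v[k]
    return d


def fa_from_eigenvalues(l1: float, l2: float, l3: float) -> float:
    """FA from tensor eigenvalues; negative eigenvalues are clamped to 0."""
    lam = np.array([l1, l2, l3], dtype=float)
    lam = np.clip(lam, 0.0, None)
    ssq = float(np.sum(lam**2))
    if ssq == 0.0:
        return 0.0
    mean = lam.mean()
    return float(np.sqrt(1.5 * np.sum((lam - mean) ** 2) / ssq))


@dataclass
class ScalarMap:
    """A voxelwise scalar metric (FA, uFA or MD) with a validity mask."""

    data: np.ndarray
    metric: str
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (2.5, 2.5, 2.5)
    affine: np.ndarray | None = None

    def __post_init__(self):
        if self.data.shape != self.mask.shape:
            raise ValueError("map and mask shapes differ")
        if self.metric in ("FA", "uFA"):
            vals = self.data[self.mask]
            if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
                raise ValueError(f"{self.metric} values outside [0, 1] in mask")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])


class DiffusionTensorModel:
    """Weighted log-linear diffusion tensor model for a signal volume.

    Parameters
    ----------
    volume
        4-D signal volume with an LTE protocol.
    mask
        Boolean 3-D array selecting voxels to fit; default all.
    shell_b
        The diffusion-weighted shell used together with b=0 (default 1000).
    b0_tol
        Entries with b <= b0_tol count as b=0.
    """

    def __init__(
        self,
        volume: SignalVolume,
        mask: np.ndarray | None = None,
        shell_b: float = 1000.0,
        b0_tol: float = 1.0,
    ):
        self.volume = volume
        self.mask = (
            np.ones(volume.data.shape[:3], dtype=bool) if mask is None else mask.astype(bool)
        )
        protocol = volume.protocol
        bvals = protocol.b_values
        use = np.zeros(len(protocol), dtype=bool)
        dirs = []
        for i, e in enumerate(protocol.encodings):
            if e.shape_label != LINEAR:
                continue
            if e.b_value <= b0_tol:
                use[i] = True
            elif abs(e.b_value - shell_b) <= 1e-6 * max(shell_b, 1.0):
                use[i] = True
                dirs.append(e.direction)
        if not np.any(bvals[use] <= b0_tol):
            raise ValueError("protocol has no b=0 entry")
        if len(dirs) >= 2:
            # rank of the symmetric outer products decides identifiability
            g = np.array(dirs)
            moment = np.stack([np.outer(d, d)[np.triu_indices(3)] for d in g])
            rank = np.linalg.matrix_rank(moment)
        else:
            rank = len(dirs)
        if rank < 6:
            raise ValueError(
                f"need >= 6 non-collinear directions at b={shell_b:g}; got rank {rank}"
            )
        self._use = use
        self._design = _design_matrix(protocol.btensors()[use])

    def fit(self) -> "DiffusionTensorResults":
        vol = self.volume.data[..., self._use]
        shape = vol.shape[:3]
        n_par = 7
        tensors = np.zeros(shape + (3, 3))
        evals = np.zeros(shape + (3,))
        s0 = np.zeros(shape)
        ok = np.zeros(shape, dtype=bool)
        clamped = np.zeros(shape, dtype=bool)
        X = self._design
        for idx in np.ndindex(shape):
            if not self.mask[idx]:
                continue
            y = vol[idx]
            if np.any(y <= 0):
                continue  # flagged: excluded from the fit
            logy = np.log(y)
            w = y**2  # weights = squared signal
            Xw = X * w[:, None]
            beta, *_ = np.linalg.lstsq(Xw.T @ X, Xw.T @ logy, rcond=None)
            d = _vec_to_tensor(beta[1:])
            lam = np.linalg.eigvalsh(d)[::-1]
            if np.any(lam < 0):
                clamped[idx] = True
                lam = np.clip(lam, 0.0, None)
            tensors[idx] = d
            evals[idx] = lam
            s0[idx] = np.exp(beta[0])
            ok[idx] = True
        return DiffusionTensorResults(self, tensors, evals, s0, ok, clamped)


@dataclass
class DiffusionTensorResults:
    """Per-voxel tensor fit: eigenvalues, FA/MD maps, QC flags."""

    model: DiffusionTensorModel
    tensors: np.ndarray
    eigenvalues: np.ndarray
    s0: np.ndarray
    ok: np.ndarray
    clamped: np.ndarray

    @property
    def md(self) -> np.ndarray:
        return self.eigenvalues.mean(axis=-1)

    @property
    def fa(self) -> np.ndarray:
        lam = self.eigenvalues
        mean = lam.mean(axis=-1, keepdims=True)
        num = np.sum((lam - mean) ** 2, axis=-1)
        den = np.sum(lam**2, axis=-1)
        out = np.zeros(lam.shape[:-1])
        nz = den > 0
        out[nz] = np.sqrt(1.5 * num[nz] / den[nz])
        return out

    def fa_map(self) -> ScalarMap:
        return ScalarMap(
            np.clip(self.fa, 0.0, 1.0), "FA", self.ok, self.model.volume.voxel_size,
            self.model.volume.affine,
        )

    def md_map(self) -> ScalarMap:
        return ScalarMap(self.md, "MD", self.ok, self.model.volume.voxel_size,
                         self.model.volume.affine)

    def summary(self) -> str:
        n = int(self.ok.sum())
        lines = [
            "Diffusion tensor fit (weighted log-linear LLS)",
            f"  voxels fitted:        {n}",
            f"  voxels clamped (<0):  {int(self.clamped.sum())}",
        ]
        if n:
            lines += [
                f"  FA   mean (fitted):   {self.fa[self.ok].mean():.4f}",
                f"  MD   mean (fitted):   {self.md[self.ok].mean():.4e} mm^2/s",
            ]
        return "\n".join(lines)


def fit_dti(volume: SignalVolume, mask: np.ndarray | None = None, **kw) -> DiffusionTensorResults:
    """Convenience wrapper: build and fit a :class:`DiffusionTensorModel`."""
    return DiffusionTensorModel(volume, mask, **kw).fit()
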