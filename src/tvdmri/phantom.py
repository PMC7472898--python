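"""Synthetic voxel environments and signal simulation.

A voxel is modelled as a mixture of axisymmetric Gaussian microdomains
("zeppelins": axial diffusivity d_par >= radial d_perp) with an
orientation structure, plus an optional isotropic compartment.  Six
canonical environments cover the situations where conventional FA and
microscopic FA (uFA) dissociate:

A  straight, coherent fibres            FA high,   uFA high (equal)
B  two orthogonal crossing populations  FA low,    uFA high
C  fanning/dispersed fibres (Watson)    FA low,    uFA high
D  straight but degenerated fibres      FA lower,  uFA lower
E  crossing with one bundle degenerated FA higher than B, uFA lower
F  lesion: mostly isotropic, fast       FA low,    uFA low

Degeneration ("damage", a latent in [0, 1]) shrinks the microscopic
anisotropy d_par - d_perp by (1 - damage) and grows an isotropic
compartment proportionally, emulating changed volume fractions of the
cellular spaces.

The noiseless signal for encoding b-tensor B is
``S = s0 * (sum_i f_i exp(-B:D_i) + f_iso exp(-b * d_iso))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .encoding import LINEAR, SPHERICAL, Protocol

__all__ = [
    "MicroDomain",
    "VoxelEnvironment",
    "Phantom",
    "SignalVolume",
    "canonical_environment",
    "simulate_signal",
    "analytic_powder_signal",
    "add_rician_noise",
    "watson_orientations",
]

# default healthy white-matter zeppelin (mm^2/s)
D_PAR_WM = 1.7e-3
D_PERP_WM = 0.2e-3
D_ISO_LESION = 2.0e-3
D_FREE = 3.5e-3  # physical ceiling near free water at body temperature


@dataclass(frozen=True)
class MicroDomain:
    """Axisymmetric Gaussian microdomain."""

    d_par: float
    d_perp: float
    orientation: np.ndarray

    def __post_init__(self):
        if not (0.0 <= self.d_perp <= self.d_par <= D_FREE):
            raise ValueError("require 0 <= d_perp <= d_par <= 3.5e-3 mm^2/s")
        n = np.asarray(self.orientation, dtype=float)
        if n.shape != (3,) or abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("orientation must be a unit 3-vector")
        object.__setattr__(self, "orientation", n)

    @property
    def tensor(self) -> np.ndarray:
        n = self.orientation
        return self.d_perp * np.eye(3) + (self.d_par - self.d_perp) * np.outer(n, n)

    @property
    def md(self) -> float:
        return (self.d_par + 2.0 * self.d_perp) / 3.0


@dataclass
class VoxelEnvironment:
    """Mixture of microdomains plus an isotropic compartment."""

    components: list[tuple[float, MicroDomain]]
    iso_fraction: float = 0.0
    iso_diffusivity: float = D_ISO_LESION
    label: str = "custom"

    def __post_init__(self):
        fracs = np.array([f for f, _ in self.components] + [self.iso_fraction])
        if np.any(fracs < 0):
            raise ValueError("fractions must be non-negative")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")

    @property
    def mean_tensor(self) -> np.ndarray:
        d = sum(f * dom.tensor for f, dom in self.components)
        return d + self.iso_fraction * self.iso_diffusivity * np.eye(3)

    @property
    def md(self) -> float:
        return float(np.trace(self.mean_tensor)) / 3.0


def watson_orientations(mu, kappa: float, n: int, seed: int) -> np.ndarray:
    """Sample ``n`` orientations from a Watson distribution about ``mu``.

    The Watson density on the sphere is proportional to exp(kappa (mu.x)^2);
    the polar cosine t = mu.x is drawn by numerically inverting its CDF on a
    dense grid (deterministic given seed), the azimuth uniformly.
    """
    rng = np.random.default_rng(seed)
    t_grid = np.linspace(-1.0, 1.0, 4001)
    pdf = np.exp(kappa * t_grid**2)
    cdf = np.cumsum(pdf)
    cdf /= cdf[-1]
    t = np.interp(rng.random(n), cdf, t_grid)
    phi = rng.random(n) * 2 * np.pi
    s = np.sqrt(np.clip(1 - t**2, 0, None))
    samples = np.column_stack([s * np.cos(phi), s * np.sin(phi), t])
    # rotate z-axis onto mu
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, mu)
    c = float(z @ mu)
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx / (1 + c)
    return samples @ rot.T


def _damaged(d_par: float, d_perp: float, damage: float) -> tuple[float, float]:
    """Shrink microscopic anisotropy by (1 - damage), keeping d_perp."""
    return d_perp + (d_par - d_perp) * (1.0 - damage), d_perp


# extra isotropic volume fraction created per unit damage
_ISO_PER_DAMAGE = 0.15


def canonical_environment(
    label: str,
    damage: float = 0.0,
    seed: int = 0,
    d_par: float = D_PAR_WM,
    d_perp: float = D_PERP_WM,
    kappa: float = 4.0,
    n_fan: int = 30,
) -> VoxelEnvironment:
    """Construct one of the canonical voxel environments A-F.

    ``damage`` in [0, 1] applies to the environments that model
    degeneration (D, E) and is ignored where the environment is defined
    without it (A, B, C); F is a lesion regardless of damage.
    """
    if not 0.0 <= damage <= 1.0:
        raise ValueError("damage must lie in [0, 1]")
    ex = np.array([1.0, 0.0, 0.0])
    ey = np.array([0.0, 1.0, 0.0])

    if label == "A":
        return VoxelEnvironment([(1.0, MicroDomain(d_par, d_perp, ex))], label="A")
    if label == "B":
        return VoxelEnvironment(
            [(0.5, MicroDomain(d_par, d_perp, ex)), (0.5, MicroDomain(d_par, d_perp, ey))],
            label="B",
        )
    if label == "C":
        dp, dr = _damaged(d_par, d_perp, damage)
        iso = _ISO_PER_DAMAGE * damage
        dirs = watson_orientations(ex, kappa, n_fan, seed)
        f = (1.0 - iso) / n_fan
        comps = [(f, MicroDomain(dp, dr, d)) for d in dirs]
        return VoxelEnvironment(comps, iso_fraction=iso, label="C")
    if label == "D":
        dp, dr = _damaged(d_par, d_perp, damage)
        iso = _ISO_PER_DAMAGE * damage
        return VoxelEnvironment(
            [(1.0 - iso, MicroDomain(dp, dr, ex))],
            iso_fraction=iso,
            label="D",
        )
    if label == "E":
        # degeneration of one crossing population: its microscopic
        # anisotropy collapses while the intact population persists, so
        # the voxel-mean tensor becomes MORE anisotropic (FA rises) while
        # the microscopic anisotropy content falls (uFA drops)
        dp, dr = _damaged(d_par, d_perp, damage)
        return VoxelEnvironment(
            [
                (0.5, MicroDomain(d_par, d_perp, ex)),
                (0.5, MicroDomain(dp, dr, ey)),
            ],
            label="E",
        )
    if label == "F":
        iso = 0.85
        return VoxelEnvironment(
            [(1.0 - iso, MicroDomain(d_par, d_perp, ex))],
            iso_fraction=iso,
            iso_diffusivity=D_ISO_LESION,
            label="F",
        )
    raise ValueError(f"unknown environment label {label!r}")


@dataclass
class Phantom:
    """A labelled 3-D grid of voxel environments with named masks."""

    grid: np.ndarray  # object array of VoxelEnvironment (or None outside)
    voxel_size: tuple[float, float, float] = (2.5, 2.5, 2.5)
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for name, m in self.masks.items():
            if m.shape != self.grid.shape:
                raise ValueError(f"mask {name!r} shape mismatch")
        nawm = self.masks.get("NAWM")
        les = self.masks.get("lesions")
        if nawm is not None and les is not None and np.any(nawm & les):
            raise ValueError("lesion mask must be disjoint from NAWM mask")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.grid.shape


@dataclass
class SignalVolume:
    """4-D signal array (x, y, z, encoding) tied to its protocol."""

    data: np.ndarray
    protocol: Protocol
    voxel_size: tuple[float, float, float] = (2.5, 2.5, 2.5)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("signal data must be 4-D")
        if self.data.shape[3] != len(self.protocol):
            raise ValueError("4th dimension must match protocol length")
        if np.any(self.data < 0):
            raise ValueError("signal values must be non-negative")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])


def _attenuation(env: VoxelEnvironment, btensors: np.ndarray, bvals: np.ndarray) -> np.ndarray:
    """Per-encoding signal fraction sum_i f_i exp(-B:D_i) + f_iso exp(-b d_iso)."""
    att = np.zeros(len(bvals))
    for f, dom in env.components:
        bd = np.einsum("kij,ij->k", btensors, dom.tensor)
        att += f * np.exp(-bd)
    if env.iso_fraction > 0:
        att += env.iso_fraction * np.exp(-bvals * env.iso_diffusivity)
    return att


def simulate_signal(phantom: Phantom, protocol: Protocol, s0: float = 1.0) -> SignalVolume:
    """Noiseless signal volume for every voxel environment in the phantom."""
    btensors = protocol.btensors()
    bvals = protocol.b_values
    shape = phantom.grid.shape
    data = np.zeros(shape + (len(protocol),))
    cache: dict[int, np.ndarray] = {}
    for idx in np.ndindex(shape):
        env = phantom.grid[idx]
        if env is None:
            continue
        key = id(env)
        att = cache.get(key)
        if att is None:
            att = _attenuation(env, btensors, bvals)
            cache[key] = att
        data[idx] = s0 * att
    return SignalVolume(data, protocol, phantom.voxel_size)


def analytic_powder_signal(domain: MicroDomain, b_value: float) -> float:
    """Exact orientation average of the LTE signal of one microdomain.

    For an axisymmetric domain the powder-averaged attenuation has the
    closed form ``exp(-b d_perp) * (sqrt(pi)/2) * erf(sqrt(b dD)) /
    sqrt(b dD)`` with ``dD = d_par - d_perp``; the isotropic limit
    dD -> 0 is ``exp(-b d_par)``.
    """
    if b_value < 0:
        raise ValueError("b-value must be non-negative")
    dd = domain.d_par - domain.d_perp
    x = b_value * dd
    if x < 1e-12:
        return float(np.exp(-b_value * domain.d_par))
    sx = np.sqrt(x)
    return float(np.exp(-b_value * domain.d_perp) * (np.sqrt(np.pi) / 2.0) * erf(sx) / sx)


def analytic_powder_environment(env: VoxelEnvironment, b_value: float) -> float:
    """Ideal powder-averaged LTE attenuation of a whole voxel environment."""
    s = sum(f * analytic_powder_signal(dom, b_value) for f, dom in env.components)
    if env.iso_fraction > 0:
        s += env.iso_fraction * np.exp(-b_value * env.iso_diffusivity)
    return float(s)


def ste_environment_signal(env: VoxelEnvironment, b_value: float) -> float:
    """Spherical-encoding attenuation: depends only on component MDs."""
    s = sum(f * np.exp(-b_value * dom.md) for f, dom in env.components)
    if env.iso_fraction > 0:
        s += env.iso_fraction * np.exp(-b_value * env.iso_diffusivity)
    return float(s)


def add_rician_noise(volume: SignalVolume, snr: float, seed: int, s0: float = 1.0) -> SignalVolume:
    """Rician (magnitude-MRI) noise at the given b=0 SNR.

    Each value v is replaced by |v + e1 + i e2| with e1, e2 ~ N(0, s0/snr).
    Deterministic given ``seed``.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    sigma = s0 / snr
    e1 = rng.normal(0.0, sigma, size=volume.data.shape)
    e2 = rng.normal(0.0, sigma, size=volume.data.shape)
    noisy = np.sqrt((volume.data + e1) ** 2 + e2**2)
    return SignalVolume(noisy, volume.protocol, volume.voxel_size, volume.affine)
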