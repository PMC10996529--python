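"""Residue-level force field: bonds, screened electrostatics, hydropathy.

Three interaction terms act between beads:

* a harmonic bond ``1/2 k (r - r0)^2`` between consecutive beads,
* a Debye-screened (Yukawa) Coulomb potential between charged beads,
  with the screening length computed from the NaCl concentration plus
  the ions of the potassium-phosphate buffer,
* an Ashbaugh–Hatch modified Lennard-Jones (MLJ) potential in which
  only the attractive branch is scaled by the pair hydropathy lambda.

To represent the kosmotropic effect of Na+ on the hydrophobic effect,
the MLJ well depth is a linear function of NaCl concentration,
``eps(c) = eps0 + slope * c`` (a ~3% increase over 0–1250 mM at the
default calibration); a constant-eps control and a recalibrated
large-system preset are provided.

Sign convention: scalar radial forces are ``-d(energy)/dr``; positive
means repulsive.  All quantities use the package units (nm, kJ/mol, e).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .constants import COULOMB, KJ_PER_KCAL, N_AVOGADRO, kt

__all__ = [
    "BufferSpec",
    "InteractionModel",
    "PairTable",
    "ionic_strength",
    "debye_length",
    "epsilon_of_salt",
    "bond_term",
    "yukawa_term",
    "mlj_term",
    "mlj_force_components",
    "hydrophobic_force_component",
]

_TWO_POW_SIXTH = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class BufferSpec:
    """Potassium-phosphate buffer composition.

    Default: 20 mM total phosphate, 70% dibasic (K2HPO4) / 30% monobasic
    (KH2PO4), the buffer of the study conditions.
    """

    total_phosphate: float = 0.020      # M
    fraction_dibasic: float = 0.70
    fraction_monobasic: float = 0.30

    def __post_init__(self) -> None:
        if self.total_phosphate < 0:
            raise ValueError("negative buffer concentration")
        if abs(self.fraction_dibasic + self.fraction_monobasic - 1.0) > 1e-9:
            raise ValueError("dibasic and monobasic fractions must sum to 1")

    @classmethod
    def none(cls) -> "BufferSpec":
        return cls(total_phosphate=0.0)


def ionic_strength(c_nacl: float, buffer: BufferSpec = BufferSpec()) -> float:
    """Ionic strength I = 1/2 sum(c_i z_i^2) in molar.

    Counts Na+/Cl- from the salt and, from the buffer, HPO4^2- (z=-2),
    H2PO4^- (z=-1) and the K+ counterions required for charge balance.
    """
    if c_nacl < 0:
        raise ValueError("negative NaCl concentration")
    c_di = buffer.total_phosphate * buffer.fraction_dibasic
    c_mono = buffer.total_phosphate * buffer.fraction_monobasic
    c_k = 2.0 * c_di + c_mono
    return 0.5 * (2.0 * c_nacl + c_k + 4.0 * c_di + c_mono)


@dataclass(frozen=True)
class InteractionModel:
    """Global force-field state.

    The default eps(c_NaCl) line is calibrated so that the well depth is
    0.1985 kcal/mol at 0 mM and 0.205 kcal/mol at 1250 mM NaCl; the
    ``large_system`` preset uses the recalibrated 0.1875–0.1905 kcal/mol
    endpoints.  ``lambda_scale``/``charge_scale`` are global multipliers
    (both 1 by default) used for mechanism-ablation scenarios.
    """

    temperature: float = 298.0              # K
    relative_permittivity: float = 78.4
    c_nacl: float = 0.0                     # M
    buffer: BufferSpec = field(default_factory=BufferSpec)
    eps0: float = 0.1985 * KJ_PER_KCAL      # kJ/mol at 0 mM NaCl
    eps_slope: float = (0.205 - 0.1985) / 1.25 * KJ_PER_KCAL  # kJ/mol per M
    salt_dependent_epsilon: bool = True
    constant_eps: float = 0.205 * KJ_PER_KCAL  # kJ/mol, fixed-eps control
    bond_k: float = 8305.0                  # kJ/(mol nm^2)
    bond_r0: float = 0.38                   # nm
    cutoff_elec: float = 3.5                # nm
    cutoff_mlj: float = 2.0                 # nm
    lambda_scale: float = 1.0
    charge_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("bond_r0", "cutoff_elec", "cutoff_mlj", "temperature",
                     "relative_permittivity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.c_nacl < 0:
            raise ValueError("negative NaCl concentration")

    # -- derived quantities ------------------------------------------------
    @property
    def kT(self) -> float:
        return kt(self.temperature)

    @property
    def ionic_strength(self) -> float:
        return ionic_strength(self.c_nacl, self.buffer)

    @property
    def debye_length(self) -> float:
        """Debye screening length, nm (requires nonzero ionic strength)."""
        return debye_length(self.c_nacl, self.buffer, self)

    @property
    def kappa(self) -> float:
        """Inverse screening length 1/lambda_D, nm^-1 (0 = unscreened)."""
        I = self.ionic_strength
        if I == 0.0:
            return 0.0
        return 1.0 / debye_length(self.c_nacl, self.buffer, self)

    @property
    def epsilon(self) -> float:
        """MLJ well depth at this model's NaCl concentration, kJ/mol."""
        return epsilon_of_salt(self.c_nacl, self)

    @property
    def coulomb_prefactor(self) -> float:
        """q_i q_j multiplier e^2/(4 pi eps_r eps_vac), kJ nm/mol."""
        return COULOMB / self.relative_permittivity

    # -- presets -----------------------------------------------------------
    def at_salt(self, c_nacl: float) -> "InteractionModel":
        return replace(self, c_nacl=c_nacl)

    @classmethod
    def constant_epsilon_control(cls, c_nacl: float = 0.0, **kw) -> "InteractionModel":
        """Control model with a fixed MLJ well depth of 0.205 kcal/mol."""
        return cls(c_nacl=c_nacl, salt_dependent_epsilon=False, **kw)

    @classmethod
    def large_system(cls, c_nacl: float = 0.0, **kw) -> "InteractionModel":
        """Recalibrated eps endpoints for the high-protein-count boxes."""
        return cls(
            c_nacl=c_nacl,
            eps0=0.1875 * KJ_PER_KCAL,
            eps_slope=(0.1905 - 0.1875) / 1.25 * KJ_PER_KCAL,
            **kw,
        )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["buffer"] = asdict(self.buffer)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "InteractionModel":
        d = dict(d)
        if "buffer" in d and isinstance(d["buffer"], dict):
            d["buffer"] = BufferSpec(**d["buffer"])
        return cls(**d)


def debye_length(c_nacl: float, buffer: BufferSpec | None = None,
                 model: InteractionModel | None = None) -> float:
    """Debye screening length in nm.

    lambda_D = sqrt(eps_r eps_vac k_B T / (2 N_A e^2 I)); strictly
    decreasing in the NaCl concentration.  Zero ionic strength has an
    infinite screening length and is rejected — request a pure-Coulomb
    model explicitly (kappa = 0) rather than passing I = 0 here.
    """
    if model is None:
        model = InteractionModel()
    if buffer is None:
        buffer = model.buffer
    I = ionic_strength(c_nacl, buffer)
    if I <= 0.0:
        raise ValueError("zero ionic strength: screening length is infinite; "
                         "use an explicit pure-Coulomb mode instead")
    # Bjerrum length l_B = e^2/(4 pi eps_vac eps_r kT); kappa^2 = 8 pi l_B n
    l_b = COULOMB / (model.relative_permittivity * model.kT)
    n_per_nm3 = I * N_AVOGADRO * 1e-24
    kappa2 = 8.0 * math.pi * l_b * n_per_nm3
    return 1.0 / math.sqrt(kappa2)


def epsilon_of_salt(c_nacl: float, model: InteractionModel | None = None) -> float:
    """Salt-dependent MLJ well depth eps(c) in kJ/mol.

    First-order perturbation eps0 + slope*c capturing the kosmotropic
    strengthening of the hydrophobic effect by NaCl; with the salt
    dependence toggled off, returns the fixed control value.
    """
    if c_nacl < 0:
        raise ValueError("negative NaCl concentration")
    if model is None:
        model = InteractionModel()
    if not model.salt_dependent_epsilon:
        return model.constant_eps
    return model.eps0 + model.eps_slope * c_nacl


def bond_term(r, model: InteractionModel | None = None):
    """Harmonic bond energy and scalar force at separation *r* (nm).

    energy = 1/2 k (r - r0)^2, force = -k (r - r0) (positive = repulsive).
    """
    if model is None:
        model = InteractionModel()
    r = np.asarray(r, dtype=float)
    energy = 0.5 * model.bond_k * (r - model.bond_r0) ** 2
    force = -model.bond_k * (r - model.bond_r0)
    return energy, force


def yukawa_term(r, qq, model: InteractionModel | None = None):
    """Screened-Coulomb pair energy and radial force.

    energy = qq e^2/(4 pi eps_r eps_vac r) exp(-r/lambda_D), truncated
    (unshifted) at the electrostatic cutoff.  *qq* is the charge product
    in e^2.
    """
    if model is None:
        model = InteractionModel()
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    kappa = model.kappa
    pref = model.coulomb_prefactor * qq
    inside = r <= model.cutoff_elec
    screen = np.exp(-kappa * r)
    energy = np.where(inside, pref * screen / r, 0.0)
    # -dE/dr = pref * exp(-kr) * (1/r^2 + k/r)
    force = np.where(inside, pref * screen * (1.0 / r**2 + kappa / r), 0.0)
    if np.ndim(r) == 0:
        return float(energy), float(force)
    return energy, force


def _lj(r, sigma, eps):
    sr6 = (sigma / r) ** 6
    e = 4.0 * eps * (sr6 * sr6 - sr6)
    f = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r  # -dE/dr
    return e, f


def mlj_term(r, sigma_ij, lambda_ij, eps, cutoff: float = 2.0):
    """Ashbaugh–Hatch modified Lennard-Jones energy and radial force.

    Full LJ shifted up by eps*(1-lambda) inside the minimum
    (r <= 2^(1/6) sigma), lambda-scaled LJ outside; continuous at the
    branch point; truncated (unshifted) at the cutoff.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    lj_e, lj_f = _lj(r, sigma_ij, eps)
    rmin = _TWO_POW_SIXTH * sigma_ij
    core = r <= rmin
    energy = np.where(core, lj_e + eps * (1.0 - lambda_ij), lambda_ij * lj_e)
    force = np.where(core, lj_f, lambda_ij * lj_f)
    outside = r > cutoff
    energy = np.where(outside, 0.0, energy)
    force = np.where(outside, 0.0, force)
    if np.ndim(r) == 0:
        return float(energy), float(force)
    return energy, force


def mlj_force_components(r, sigma_ij, lambda_ij, eps, cutoff: float = 2.0):
    """Split the MLJ radial force into (repulsive, hydrophobic) parts.

    The decomposition is phi_MLJ = phi_rep + lambda * phi_att with
    phi_att = LJ + eps inside the minimum and LJ outside, so the
    hydrophobic (lambda-weighted attractive) force component equals
    lambda times the plain 12-6 LJ radial force at every r within the
    cutoff, and the full MLJ force beyond the branch point.
    """
    r = np.asarray(r, dtype=float)
    _, lj_f = _lj(r, sigma_ij, eps)
    hydro = np.where(r > cutoff, 0.0, lambda_ij * lj_f)
    _, total = mlj_term(r, sigma_ij, lambda_ij, eps, cutoff)
    rep = total - hydro
    if np.ndim(r) == 0:
        return float(rep), float(hydro)
    return rep, hydro


def hydrophobic_force_component(r, sigma_ij, lambda_ij, eps, cutoff: float = 2.0):
    """The lambda-weighted (hydrophobic) component of the MLJ force."""
    return mlj_force_components(r, sigma_ij, lambda_ij, eps, cutoff)[1]


@dataclass(frozen=True)
class PairTable:
    """Mixing-rule tables over residue types.

    sigma_ij and lambda_ij are arithmetic means of the per-residue
    values; qq_ij is the charge product in e^2.  Symmetric by
    construction.
    """

    residues: str
    sigma: np.ndarray
    lam: np.ndarray
    qq: np.ndarray

    @classmethod
    def from_params(cls, table: dict | None = None) -> "PairTable":
        from .chain import residue_params
        table = table or residue_params()
        codes = "".join(sorted(table))
        s = np.array([table[a].size for a in codes])
        l = np.array([table[a].hydropathy for a in codes])
        q = np.array([float(table[a].charge) for a in codes])
        return cls(
            residues=codes,
            sigma=0.5 * (s[:, None] + s[None, :]),
            lam=0.5 * (l[:, None] + l[None, :]),
            qq=q[:, None] * q[None, :],
        )

    def to_frame(self, which: str = "sigma"):
        import pandas as pd
        mat = getattr(self, {"sigma": "sigma", "lambda": "lam", "qq": "qq"}[which])
        return pd.DataFrame(mat, index=list(self.residues), columns=list(self.residues))
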