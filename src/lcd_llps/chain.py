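"""Chain specifications for the TDP-43 LCD construct and its variants.

Each amino acid is a single coarse-grained bead with four properties —
mass m (amu), charge q (elementary charges), hydropathy lambda (the
Kapcha–Rossky scale, normalised to [0, 1]) and size sigma (nm).  The
151-residue construct is the thrombin-cleaved low-complexity domain
(GS + TDP-43 residues 266–414); phosphomimetic and control variants are
derived from it by point substitution, never stored separately.

TDP-43 numbering (e.g. "S403") is canonical in the API and is mapped to
1-based construct positions through a fixed offset.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from io import StringIO
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ResidueParams",
    "ChainSpec",
    "CANONICAL_RESIDUES",
    "TDP43_OFFSET",
    "VARIANT_SUBSTITUTIONS",
    "load_residue_params",
    "construct_sequence",
    "tdp43_to_construct",
    "construct_to_tdp43",
    "build_variant",
    "net_charge",
    "ncpr_profile",
    "extinction_coefficient_280",
    "read_fasta",
    "write_fasta",
]

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: construct position (1-based) = TDP-43 residue number - TDP43_OFFSET.
TDP43_OFFSET = 263

_CONSTRUCT_MD5 = "70db8d609b3f5254535102898545a0f0"

#: Substitutions defining each named variant, in TDP-43 numbering.
VARIANT_SUBSTITUTIONS: dict[str, dict[int, str]] = {
    "WT": {},
    "2PM": {403: "D", 404: "D"},
    "4PM": {403: "D", 404: "D", 409: "D", 410: "D"},
    "4PM_A326P": {403: "D", 404: "D", 409: "D", 410: "D", 326: "P"},
    "4PM_W334G": {403: "D", 404: "D", 409: "D", 410: "D", 334: "G"},
}

# Extinction coefficients at 280 nm, M^-1 cm^-1 (Gill & von Hippel
# composition rule; cystines ignored — the construct has no Cys).
_EPS_TRP = 5500.0
_EPS_TYR = 1490.0


@dataclass(frozen=True)
class ResidueParams:
    """Coarse-grained bead parameters for one amino-acid type."""

    residue: str
    mass: float        # amu
    charge: int        # elementary charges: -1 (D/E), +1 (K/R), else 0
    hydropathy: float  # dimensionless lambda in [0, 1]
    size: float        # sigma, nm

    def __post_init__(self) -> None:
        if self.residue not in CANONICAL_RESIDUES:
            raise KeyError(f"non-canonical residue code {self.residue!r}")
        if not (np.isfinite(self.hydropathy) and self.hydropathy >= 0.0):
            raise ValueError("hydropathy must be finite and non-negative")
        if not (np.isfinite(self.size) and self.size > 0.0):
            raise ValueError("size must be finite and positive")
        if not (np.isfinite(self.mass) and self.mass > 0.0):
            raise ValueError("mass must be finite and positive")


def _read_packaged(name: str) -> str:
    return resources.files("lcd_llps.data").joinpath(name).read_text()


def load_residue_params() -> dict[str, ResidueParams]:
    """Load and validate the packaged 20-residue parameter table.

    The table carries, per canonical residue, the bead mass, integer
    charge, Kapcha–Rossky hydropathy and van-der-Waals diameter used by
    the HPS-class force field.
    """
    df = pd.read_csv(StringIO(_read_packaged("hps_kr_params.tsv")), sep="\t")
    expected = ["residue", "mass_amu", "charge_e", "lambda", "sigma_nm"]
    if list(df.columns) != expected:
        raise ValueError(f"parameter table columns {list(df.columns)} != {expected}")
    if sorted(df["residue"]) != sorted(CANONICAL_RESIDUES):
        raise ValueError("parameter table must contain exactly the 20 canonical residues")
    table = {}
    for row in df.itertuples(index=False):
        expected_q = -1 if row.residue in "DE" else (1 if row.residue in "KR" else 0)
        if int(row.charge_e) != expected_q:
            raise ValueError(f"unexpected charge for {row.residue}")
        table[row.residue] = ResidueParams(
            residue=row.residue,
            mass=float(row.mass_amu),
            charge=int(row.charge_e),
            hydropathy=float(getattr(row, "_3")),  # 'lambda' is a keyword
            size=float(row.sigma_nm),
        )
    return table


_PARAMS: dict[str, ResidueParams] | None = None


def residue_params() -> dict[str, ResidueParams]:
    global _PARAMS
    if _PARAMS is None:
        _PARAMS = load_residue_params()
    return _PARAMS


def construct_sequence() -> str:
    """The 151-residue construct sequence, checksum-verified on load."""
    rec = next(SeqIO.parse(StringIO(_read_packaged("tdp43_lcd_construct.fasta")), "fasta"))
    seq = str(rec.seq)
    if hashlib.md5(seq.encode()).hexdigest() != _CONSTRUCT_MD5:
        raise RuntimeError("packaged construct sequence failed its checksum")
    return seq


def tdp43_to_construct(pos: int) -> int:
    """Map a TDP-43 residue number (266–414) to a 1-based construct position."""
    idx = pos - TDP43_OFFSET
    if not 3 <= idx <= 151:
        raise ValueError(f"TDP-43 residue {pos} is outside the construct (266-414)")
    return idx


def construct_to_tdp43(idx: int) -> int | None:
    """Map a 1-based construct position to TDP-43 numbering.

    The two N-terminal residues left by thrombin cleavage have no
    TDP-43 number and map to ``None``.
    """
    if not 1 <= idx <= 151:
        raise ValueError(f"construct position {idx} out of range 1-151")
    return None if idx < 3 else idx + TDP43_OFFSET


@dataclass
class ChainSpec:
    """A fully parameterised coarse-grained chain (one protein)."""

    variant_id: str
    sequence: str
    beads: list[ResidueParams] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.beads) != len(self.sequence):
            raise ValueError("bead list and sequence length differ")

    @property
    def length(self) -> int:
        return len(self.sequence)

    # Cached per-bead arrays in simulator layout.
    @property
    def masses(self) -> np.ndarray:
        return np.array([b.mass for b in self.beads])

    @property
    def charges(self) -> np.ndarray:
        return np.array([float(b.charge) for b in self.beads])

    @property
    def hydropathies(self) -> np.ndarray:
        return np.array([b.hydropathy for b in self.beads])

    @property
    def sizes(self) -> np.ndarray:
        return np.array([b.size for b in self.beads])

    @property
    def molecular_weight(self) -> float:
        """Sum of residue masses, amu (termini not adjusted)."""
        return float(self.masses.sum())


def _parameterize(variant_id: str, sequence: str) -> ChainSpec:
    table = residue_params()
    try:
        beads = [table[a] for a in sequence]
    except KeyError as err:
        raise KeyError(f"sequence contains non-canonical residue {err.args[0]!r}") from None
    return ChainSpec(variant_id=variant_id, sequence=sequence, beads=beads)


def build_variant(variant_id: str, sequence: str | None = None) -> ChainSpec:
    """Build a parameterised chain for a named variant or a custom sequence.

    Parameters
    ----------
    variant_id
        One of ``WT``, ``2PM``, ``4PM``, ``4PM_A326P``, ``4PM_W334G`` or
        ``custom`` (in which case *sequence* must be given).
    sequence
        One-letter sequence, only for ``variant_id='custom'``.
    """
    if variant_id == "custom":
        if not sequence:
            raise ValueError("variant 'custom' requires an explicit sequence")
        return _parameterize("custom", sequence)
    if variant_id not in VARIANT_SUBSTITUTIONS:
        raise KeyError(f"unknown variant {variant_id!r}; known: "
                       f"{sorted(VARIANT_SUBSTITUTIONS)} or 'custom'")
    if sequence is not None:
        raise ValueError("sequence may only be given with variant 'custom'")
    seq = list(construct_sequence())
    for tdp_pos, aa in VARIANT_SUBSTITUTIONS[variant_id].items():
        seq[tdp43_to_construct(tdp_pos) - 1] = aa
    return _parameterize(variant_id, "".join(seq))


def net_charge(chain: ChainSpec) -> int:
    """Net charge in elementary charges (termini contribute zero)."""
    return int(round(sum(b.charge for b in chain.beads)))


def ncpr_profile(chain: ChainSpec, window: int = 5) -> pd.DataFrame:
    """Sliding-window net charge per residue (NCPR).

    Returns a frame with one row per window, reported at the window
    *center* position: columns ``position`` (1-based construct index of
    the center), ``tdp43_position`` (or <NA> for positions without a
    TDP-43 number) and ``ncpr`` (mean charge over the window).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > chain.length:
        raise ValueError(f"window {window} larger than chain length {chain.length}")
    q = chain.charges
    kernel = np.ones(window) / window
    prof = np.convolve(q, kernel, mode="valid")
    starts = np.arange(1, chain.length - window + 2)
    centers = starts + window // 2
    tdp = [construct_to_tdp43(int(c)) if chain.variant_id != "custom" else None
           for c in centers]
    return pd.DataFrame({
        "position": centers,
        "tdp43_position": pd.array(tdp, dtype="Int64"),
        "ncpr": prof,
    })


def extinction_coefficient_280(chain: ChainSpec) -> float:
    """Molar absorptivity at 280 nm from Trp/Tyr composition, M^-1 cm^-1."""
    return (_EPS_TRP * chain.sequence.count("W")
            + _EPS_TYR * chain.sequence.count("Y"))


def write_fasta(chains: ChainSpec | list[ChainSpec], path) -> None:
    if isinstance(chains, ChainSpec):
        chains = [chains]
    recs = [SeqRecord(Seq(c.sequence), id=c.variant_id, description="") for c in chains]
    SeqIO.write(recs, path, "fasta")


def read_fasta(path) -> list[ChainSpec]:
    """Read sequences from FASTA as custom (but fully parameterised) chains."""
    return [_parameterize(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
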