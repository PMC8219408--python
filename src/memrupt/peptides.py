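"""Amphipathic peptide series design, masses, and helical-wheel geometry.

The peptide family modelled here is a minimal binary-encoded ("bien")
amphipathic helix built from arginine (cationic face) and leucine
(hydrophobic face), with a single mutation slot X in the hydrophobic face:

    R L L R L X L R L L R        (X = A -> "bienA", X = K -> "bienK")

Truncated variants (7-11 residues, end-anchored windows of the template)
form the two series whose membrane-disruption modes differ: the alanine
series porates bilayers, the lysine series produces upper-leaflet fractal
ruptures.  All synthesized members are C-terminally amidated.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "TEMPLATE",
    "PeptideSequence",
    "HelixProjection",
    "CompositionStats",
    "UnknownResidueError",
    "UndefinedRatioError",
    "build_series",
    "average_mass",
    "monoisotopic_mass",
    "wheel_projection",
    "hydrophobic_cationic_ratio",
    "read_fasta",
    "write_fasta",
]

#: Series template; ``X`` marks the mutation slot (0-based index 5).
TEMPLATE = "RLLRLXLRLLR"

CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")

# Standard residue (amino acid minus water) masses, Da.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
MONOISOTOPIC_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER_AVERAGE = 18.0153
WATER_MONOISOTOPIC = 18.010565
# C-terminal -OH -> -NH2 on amidation.
AMIDE_CORRECTION_AVERAGE = -0.9847
AMIDE_CORRECTION_MONOISOTOPIC = -0.98402


class UnknownResidueError(ValueError):
    """A residue code outside the 20 canonical amino acids."""


class UndefinedRatioError(ValueError):
    """Hydrophobic/cationic ratio requested for a sequence with no cationic residues."""


@dataclass(frozen=True)
class PeptideSequence:
    """An amino-acid sequence with an optional C-terminal amide.

    Parameters
    ----------
    residues:
        One-letter codes, N to C terminus.
    c_terminal_amide:
        True for peptides synthesized on Rink-amide resin (the whole series).
    name:
        Free label, e.g. ``"bienK_9"``.
    mutation_index:
        0-based position of the template mutation slot within this sequence,
        if the peptide was derived from the series template; None otherwise.
    """

    residues: str
    c_terminal_amide: bool = False
    name: str = ""
    mutation_index: int | None = None

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("peptide must contain at least one residue")
        for code in self.residues:
            if code not in CANONICAL:
                raise UnknownResidueError(f"unknown residue code {code!r}")
        if self.mutation_index is not None and not (
            0 <= self.mutation_index < len(self.residues)
        ):
            raise ValueError("mutation_index outside sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class HelixProjection:
    """Azimuthal helical-wheel positions for an ideal alpha helix.

    With 3.6 residues per turn, consecutive residues are 100 degrees apart
    when projected down the helix axis.
    """

    angles: tuple[float, ...]
    face_labels: tuple[str, ...]
    degrees_per_residue: float = 100.0


@dataclass(frozen=True)
class CompositionStats:
    """Hydrophobic (L, A) vs cationic (R, K) residue counts."""

    n_hydrophobic: int
    n_cationic: int

    @property
    def ratio(self) -> float:
        if self.n_cationic == 0:
            raise UndefinedRatioError("no cationic residues: ratio undefined")
        return self.n_hydrophobic / self.n_cationic


def _template_string(template: str | PeptideSequence) -> tuple[str, int]:
    """Return (template residues with X, X index)."""
    if isinstance(template, PeptideSequence):
        if template.mutation_index is None:
            raise ValueError("PeptideSequence template requires mutation_index")
        seq = list(template.residues)
        idx = template.mutation_index
        seq[idx] = "X"
        return "".join(seq), idx
    if template.count("X") != 1:
        raise ValueError("string template must contain exactly one 'X' slot")
    return template, template.index("X")


def build_series(
    template: str | PeptideSequence = TEMPLATE,
    mutation_residue: str = "A",
    lengths: list[int] | range = range(7, 12),
    truncation_end: str = "C",
) -> list[PeptideSequence]:
    """Construct the truncation series from the 11-mer template.

    Each member is a contiguous end-anchored window of the template: for
    ``truncation_end="C"`` the C-terminal window (N-terminal residues
    removed), for ``"N"`` the N-terminal window.  The mutation slot X is
    substituted with ``mutation_residue`` and must survive truncation.
    All members are C-terminally amidated, as synthesized.
    """
    seq, x_idx = _template_string(template)
    if len(seq) != 11:
        raise ValueError(f"template must be 11 residues, got {len(seq)}")
    if mutation_residue not in {"A", "K"}:
        raise ValueError("mutation_residue must be 'A' or 'K'")
    if truncation_end not in {"N", "C"}:
        raise ValueError("truncation_end must be 'N' or 'C'")

    out = []
    for n in lengths:
        if not 7 <= n <= 11:
            raise ValueError(f"invalid series length {n}: must be in 7..11")
        if truncation_end == "C":
            window = seq[len(seq) - n :]
            new_x = x_idx - (len(seq) - n)
        else:
            window = seq[:n]
            new_x = x_idx
        if not 0 <= new_x < n:
            raise ValueError(
                f"mutation slot truncated away at length {n} ({truncation_end}-anchored)"
            )
        residues = window[:new_x] + mutation_residue + window[new_x + 1 :]
        out.append(
            PeptideSequence(
                residues,
                c_terminal_amide=True,
                name=f"bien{mutation_residue}_{n}",
                mutation_index=new_x,
            )
        )
    return out


def _mass(p: PeptideSequence, table: dict, water: float, amide: float) -> float:
    total = water
    for code in p.residues:
        try:
            total += table[code]
        except KeyError:  # pragma: no cover - __post_init__ already guards
            raise UnknownResidueError(f"unknown residue code {code!r}") from None
    if p.c_terminal_amide:
        total += amide
    return total


def average_mass(p: PeptideSequence) -> float:
    """Average (isotope-abundance-weighted) molecular mass in Da.

    Sum of average residue masses plus one water, minus 0.9847 Da when the
    C terminus is amidated (OH -> NH2).  Matches the series' reported
    "calc" MS values to within +/-0.2 Da.
    """
    return _mass(p, AVERAGE_RESIDUE_MASS, WATER_AVERAGE, AMIDE_CORRECTION_AVERAGE)


def monoisotopic_mass(p: PeptideSequence) -> float:
    """Monoisotopic molecular mass in Da (companion to :func:`average_mass`)."""
    return _mass(
        p, MONOISOTOPIC_RESIDUE_MASS, WATER_MONOISOTOPIC, AMIDE_CORRECTION_MONOISOTOPIC
    )


def wheel_projection(
    p: PeptideSequence, degrees_per_residue: float = 100.0
) -> HelixProjection:
    """Project residues onto the helical wheel (3.6 residues/turn by default).

    Residue i (1-based) sits at ``(i - 1) * degrees_per_residue mod 360``.
    Faces: R/K are cationic, the mutation-slot residue is labelled
    ``"mutation"``, everything else hydrophobic.
    """
    angles = tuple(
        float((i * degrees_per_residue) % 360.0) for i in range(len(p.residues))
    )
    labels = []
    for i, code in enumerate(p.residues):
        if p.mutation_index is not None and i == p.mutation_index:
            labels.append("mutation")
        elif code in {"R", "K"}:
            labels.append("cationic")
        else:
            labels.append("hydrophobic")
    return HelixProjection(angles, tuple(labels), degrees_per_residue)


def hydrophobic_cationic_ratio(p: PeptideSequence) -> CompositionStats:
    """Count hydrophobic (L, A) and cationic (R, K) residues.

    Lysine counts as cationic even when it sits in the hydrophobic face:
    the ratio follows standard charge classification.  Raises if the
    sequence contains residues outside {R, L, A, K}.
    """
    extra = set(p.residues) - set("RLAK")
    if extra:
        raise ValueError(f"series composition stats defined over R/L/A/K only, got {sorted(extra)}")
    n_h = sum(1 for c in p.residues if c in "LA")
    n_c = sum(1 for c in p.residues if c in "RK")
    stats = CompositionStats(n_h, n_c)
    if n_c == 0:
        raise UndefinedRatioError("no cationic residues: ratio undefined")
    return stats


# ---------------------------------------------------------------------------
# FASTA I/O: description line carries the name plus "|amide" for amidated
# peptides (plain single-letter FASTA otherwise).


def write_fasta(peptides: list[PeptideSequence], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    for i, p in enumerate(peptides):
        name = p.name or f"peptide_{i + 1}"
        desc = "amide" if p.c_terminal_amide else ""
        records.append(SeqRecord(Seq(p.residues), id=f"{name}|{desc}" if desc else name,
                                 description=""))
    seqio_write(records, str(path), "fasta")


def read_fasta(path) -> list[PeptideSequence]:
    from Bio.SeqIO import parse as seqio_parse

    peptides = []
    for rec in seqio_parse(str(path), "fasta"):
        ident = rec.id
        amide = False
        if "|" in ident:
            ident, flag = ident.split("|", 1)
            amide = flag.strip().lower() == "amide"
        peptides.append(
            PeptideSequence(str(rec.seq).upper(), c_terminal_amide=amide, name=ident)
        )
    return peptides
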