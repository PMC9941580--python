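"""Per-protein physicochemical properties and intron counts.

Molecular weight uses average (isotope-abundance weighted) residue masses
plus one water; the isoelectric point is the unique root of the
Henderson-Hasselbalch net-charge function, found by bisection.  The pKa
table is configurable because published tables (EMBOSS, Bjellqvist, ...)
shift computed pI values by a few tenths of a pH unit; the default follows
the EMBOSS convention.
"""

from __future__ import annotations

from .io import GeneModel

#: Average residue masses in Daltons (monomer mass minus water), per the
#: standard amino-acid mass table used by common web calculators.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524

#: EMBOSS-style pKa values: termini plus ionizable side chains.
EMBOSS_PKA = {
    "Nterm": 8.6, "Cterm": 3.6,
    "K": 10.8, "R": 12.5, "H": 6.5,       # positive at low pH
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,  # negative at high pH
}
POSITIVE_RESIDUES = ("K", "R", "H")
NEGATIVE_RESIDUES = ("D", "E", "C", "Y")


def _validate(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty protein sequence")
    for pos, aa in enumerate(sequence, start=1):
        if aa not in AVERAGE_RESIDUE_MASS:
            raise ValueError(f"illegal amino acid {aa!r} at position {pos}")


def molecular_weight(sequence: str) -> float:
    """Average molecular weight in Daltons: residue masses plus one water."""
    _validate(sequence)
    return sum(AVERAGE_RESIDUE_MASS[aa] for aa in sequence) + WATER_MASS


def net_charge(sequence: str, ph: float, pka: dict[str, float] = EMBOSS_PKA) -> float:
    """Net protein charge at ``ph`` from Henderson-Hasselbalch terms.

    Positive groups (N-terminus, K, R, H) contribute 1/(1 + 10^(pH - pKa));
    negative groups (C-terminus, D, E, C, Y) contribute
    -1/(1 + 10^(pKa - pH)).  Strictly decreasing in pH.
    """
    charge = 1.0 / (1.0 + 10 ** (ph - pka["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (pka["Cterm"] - ph))
    for aa in sequence:
        if aa in POSITIVE_RESIDUES:
            charge += 1.0 / (1.0 + 10 ** (ph - pka[aa]))
        elif aa in NEGATIVE_RESIDUES:
            charge -= 1.0 / (1.0 + 10 ** (pka[aa] - ph))
    return charge


def isoelectric_point(
    sequence: str,
    pka: dict[str, float] = EMBOSS_PKA,
    charge_tol: float = 1e-4,
    ph_tol: float = 1e-4,
) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    The charge function is strictly decreasing, so the root is unique;
    iteration stops when |charge| < ``charge_tol`` or the bracket is
    narrower than ``ph_tol``.
    """
    _validate(sequence)
    lo, hi = 0.0, 14.0
    mid = 7.0
    while hi - lo > ph_tol:
        mid = 0.5 * (lo + hi)
        c = net_charge(sequence, mid, pka)
        if abs(c) < charge_tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return mid


def count_introns(genes: dict[str, GeneModel], gene_id: str, transcript_id: str | None = None) -> int:
    """Intron count (exons - 1) of the selected transcript of a gene.

    When ``transcript_id`` is omitted the transcript with the largest
    coding length is used, matching the longest-isoform selection rule.
    """
    gene = genes[gene_id]
    if not gene.transcripts:
        raise ValueError(f"gene {gene_id} has no transcripts with exons")
    if transcript_id is None:
        transcript_id = min(
            gene.transcripts,
            key=lambda t: (-gene.transcripts[t].coding_length, t),
        )
    tr = gene.transcripts[transcript_id]
    if not tr.exons:
        raise ValueError(f"transcript {transcript_id} has no exon features")
    return tr.n_introns
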