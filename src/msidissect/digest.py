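"""In silico tryptic digestion, peptide [M+H]+ masses, acquisition-window
filtering and proteome-uniqueness checking.

Trypsin cleaves C-terminal to K or R except when the following residue is
proline. Peptides carry monoisotopic and average protonated masses computed
from the standard residue-mass tables; the matching species is [M+H]+
(positive-mode MALDI), with cysteine unmodified since the tissue protocol
includes no alkylation step. Uniqueness against a reference proteome treats
isoleucine and leucine as equivalent, since they are isobaric and thus
indistinguishable by mass spectrometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .msi_io import ProteinRecord

logger = logging.getLogger("msidissect")

# Standard residue masses (Da). Monoisotopic values to 5 decimals; average
# values to 4. Unmodified cysteine.
MONOISOTOPIC = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
AVERAGE = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
MASS_H2O_MONO = 18.010565
MASS_H2O_AVG = 18.01528
MASS_PROTON = 1.007276

DEFAULT_MASS_RANGE = (600.0, 3200.0)


@dataclass
class TrypticPeptide:
    """One tryptic digestion product of a parent protein.

    ``start``/``end`` are 1-based inclusive residue positions;
    ``missed_cleavages`` counts uncut internal K/R sites; ``mh_mono`` and
    ``mh_avg`` are the protonated masses; ``unique_in_proteome`` is None
    until a uniqueness check has been run.
    """

    sequence: str
    parent_accession: str
    start: int
    end: int
    missed_cleavages: int
    mh_mono: float
    mh_avg: float
    unique_in_proteome: bool | None = None

    def __len__(self) -> int:
        return len(self.sequence)


def peptide_mh(sequence: str, kind: str = "mono") -> float:
    """Protonated peptide mass: sum of residue masses + H2O + proton."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    if kind == "mono":
        table, water = MONOISOTOPIC, MASS_H2O_MONO
    elif kind == "avg":
        table, water = AVERAGE, MASS_H2O_AVG
    else:
        raise ValueError(f"kind must be 'mono' or 'avg', got {kind!r}")
    try:
        total = sum(table[r] for r in sequence)
    except KeyError as exc:
        raise ValueError(f"illegal residue {exc.args[0]!r} in peptide") from exc
    return total + water + MASS_PROTON


def cleavage_sites(sequence: str) -> list[int]:
    """0-based positions i such that trypsin cuts between residue i and i+1
    (after K/R, not before P)."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(protein: ProteinRecord, max_missed: int = 1) -> list[TrypticPeptide]:
    """All tryptic peptides of ``protein`` with 0..max_missed missed cleavages.

    Peptides are returned ordered by start position then missed-cleavage
    count. The zero-missed peptides, concatenated in order, reconstruct the
    parent sequence exactly.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = protein.sequence
    # fragment boundaries: [0, site+1 ..., len]
    cuts = [0] + [s + 1 for s in cleavage_sites(seq)] + [len(seq)]
    peptides: list[TrypticPeptide] = []
    n_frag = len(cuts) - 1
    for i in range(n_frag):
        for missed in range(0, max_missed + 1):
            j = i + missed + 1
            if j > n_frag:
                break
            sub = seq[cuts[i] : cuts[j]]
            peptides.append(
                TrypticPeptide(
                    sequence=sub,
                    parent_accession=protein.accession,
                    start=cuts[i] + 1,
                    end=cuts[j],
                    missed_cleavages=missed,
                    mh_mono=peptide_mh(sub, "mono"),
                    mh_avg=peptide_mh(sub, "avg"),
                )
            )
    peptides.sort(key=lambda p: (p.start, p.missed_cleavages))
    return peptides


def filter_mass_range(
    peptides: list[TrypticPeptide],
    low: float = DEFAULT_MASS_RANGE[0],
    high: float = DEFAULT_MASS_RANGE[1],
) -> list[TrypticPeptide]:
    """Keep peptides whose monoisotopic [M+H]+ lies in the closed interval
    [low, high] — the acquisition window in which they are observable."""
    if low >= high:
        raise ValueError("low must be < high")
    return [p for p in peptides if low <= p.mh_mono <= high]


def _collapse_il(sequence: str) -> str:
    return sequence.replace("I", "L")


@dataclass
class Proteome:
    """A reference proteome indexed for I/L-insensitive substring lookup."""

    records: list[ProteinRecord]
    _collapsed: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        accs = [r.accession for r in self.records]
        if len(set(accs)) != len(accs):
            dupes = sorted({a for a in accs if accs.count(a) > 1})
            raise ValueError(f"duplicate accessions in proteome: {', '.join(dupes)}")
        self._collapsed = {r.accession: _collapse_il(r.sequence) for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def records_containing(self, peptide_sequence: str) -> list[str]:
        """Accessions whose I/L-collapsed sequence contains the peptide."""
        needle = _collapse_il(peptide_sequence)
        return [acc for acc, seq in self._collapsed.items() if needle in seq]


def check_uniqueness(peptide: TrypticPeptide, proteome: Proteome) -> bool:
    """True iff the I/L-collapsed peptide occurs in exactly one proteome
    record (its parent). Sets ``peptide.unique_in_proteome`` as a side effect.
    """
    hits = proteome.records_containing(peptide.sequence)
    if peptide.parent_accession not in hits:
        raise RuntimeError(
            f"internal consistency error: peptide {peptide.sequence!r} not "
            f"found in its own parent {peptide.parent_accession}"
        )
    peptide.unique_in_proteome = len(hits) == 1
    return peptide.unique_in_proteome


def select_marker_peptides(
    protein: ProteinRecord,
    proteome: Proteome,
    n: int = 2,
    max_missed: int = 1,
    mass_range: tuple[float, float] = DEFAULT_MASS_RANGE,
) -> list[TrypticPeptide]:
    """The n best proteome-unique peptides of a marker protein.

    Pipeline: digest -> acquisition-window filter -> uniqueness filter ->
    rank by fewest missed cleavages, then descending mass (the sparser end of
    a peptide spectrum), keep the top n. If fewer than n unique in-window
    peptides exist, returns what exists with a warning — never fabricates.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    candidates = filter_mass_range(digest(protein, max_missed=max_missed), *mass_range)
    # the same sequence can occur at several positions; uniqueness is per sequence
    seen: set[str] = set()
    unique: list[TrypticPeptide] = []
    for pep in candidates:
        if pep.sequence in seen:
            continue
        seen.add(pep.sequence)
        if check_uniqueness(pep, proteome):
            unique.append(pep)
    unique.sort(key=lambda p: (p.missed_cleavages, -p.mh_mono))
    if len(unique) < n:
        logger.warning(
            "select_marker_peptides: %s has only %d unique in-window peptide(s), "
            "%d requested",
            protein.accession,
            len(unique),
            n,
        )
    return unique[:n]


def peptides_to_dataframe(peptides: list[TrypticPeptide]):
    """Tabulate peptides (accession, sequence, positions, masses, uniqueness)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "accession": p.parent_accession,
                "sequence": p.sequence,
                "start": p.start,
                "end": p.end,
                "missed_cleavages": p.missed_cleavages,
                "mh_mono": p.mh_mono,
                "mh_avg": p.mh_avg,
                "unique": p.unique_in_proteome,
            }
            for p in peptides
        ]
    )
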