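"""Locus alignments: FASTA I/O, curation filters, and phased-haplotype handling.

A :class:`LocusAlignment` is the unit of every site-pattern computation in the
package: one anchored locus, one row per taxon, columns over the DNA alphabet
plus IUPAC ambiguity codes, the gap character ``-`` and the missing-data
characters ``N``/``?``.

Curation follows the usual anchored-phylogenomics recipe: drop columns that
are mostly gap, flag consensus sequences with an excess of ambiguous base
calls (a paralogy symptom), and exclude coding sequences containing premature
stop codons.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .errors import AlignmentShapeError, DuplicateTaxonError

#: IUPAC ambiguity codes that denote partial information (N excluded: treated
#: as missing data, not an ambiguous call, throughout the package).
AMBIGUITY_CODES = frozenset("RYSWKMBDHVryswkmbdhv")
GAP_CHARS = frozenset("-")
MISSING_CHARS = frozenset("Nn?")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# byte -> nucleotide code lookup: A=0, C=1, G=2, T/U=3, everything else -1
_CODE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _CODE_LUT[ord(_c)] = _i
    _CODE_LUT[ord(_c.lower())] = _i
_CODE_LUT[ord("U")] = _CODE_LUT[ord("u")] = 3

_DECODE = np.frombuffer(b"ACGT", dtype="S1")


def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence string to int8 codes (A=0,C=1,G=2,T=3, other=-1)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_LUT[raw]


@dataclass
class LocusAlignment:
    """One locus: an ordered taxon -> aligned sequence table."""

    locus_id: str
    taxa: list[str]
    sequences: list[str]
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise AlignmentShapeError(
                f"{self.locus_id}: {len(self.taxa)} taxa but {len(self.sequences)} sequences"
            )
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise DuplicateTaxonError(f"{self.locus_id}: duplicate taxa {dupes}")
        if any(not t for t in self.taxa):
            raise DuplicateTaxonError(f"{self.locus_id}: empty taxon label")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentShapeError(
                f"{self.locus_id}: ragged sequence lengths {sorted(lengths)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def sequence(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]

    def codes(self) -> np.ndarray:
        """(n_taxa, length) int8 matrix of nucleotide codes; cached."""
        if self._codes is None:
            if self.sequences:
                self._codes = np.vstack([encode_sequence(s) for s in self.sequences])
            else:
                self._codes = np.empty((0, 0), dtype=np.int8)
        return self._codes

    def row(self, taxon: str) -> np.ndarray:
        return self.codes()[self.taxa.index(taxon)]

    def subset(self, taxa: list[str]) -> "LocusAlignment":
        idx = {t: i for i, t in enumerate(self.taxa)}
        return LocusAlignment(
            self.locus_id, list(taxa), [self.sequences[idx[t]] for t in taxa]
        )


def read_fasta(path, locus_id: str | None = None) -> LocusAlignment:
    """Read one aligned FASTA file (wrapped or unwrapped) into a LocusAlignment.

    Raises ``AlignmentShapeError`` on ragged records and ``DuplicateTaxonError``
    on repeated labels; record order is preserved.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentShapeError(f"{path}: no FASTA records")
    name = locus_id if locus_id is not None else _stem(path)
    return LocusAlignment(name, [r.id for r in records], [str(r.seq) for r in records])


def write_fasta(aln: LocusAlignment, path, wrap: int | None = None) -> None:
    records = [
        SeqRecord(Seq(s), id=t, description="") for t, s in zip(aln.taxa, aln.sequences)
    ]
    if wrap:
        SeqIO.write(records, str(path), "fasta")
    else:
        SeqIO.write(records, str(path), "fasta-2line")


def _stem(path) -> str:
    s = str(path).rsplit("/", 1)[-1]
    return s.rsplit(".", 1)[0] if "." in s else s


def strip_gappy_columns(
    aln: LocusAlignment, max_gap_fraction: float = 0.8
) -> tuple[LocusAlignment, np.ndarray]:
    """Remove columns whose gap fraction strictly exceeds ``max_gap_fraction``.

    Gap means ``-`` only; ``N``/``?`` count as missing data, not gap. Returns
    the filtered alignment together with the retained original column indices
    (provenance map). A column at exactly the threshold is kept.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    if aln.n_taxa == 0 or aln.length == 0:
        return aln, np.arange(aln.length)
    mat = np.vstack(
        [np.frombuffer(s.encode("ascii"), dtype=np.uint8) for s in aln.sequences]
    )
    gap_frac = (mat == ord("-")).mean(axis=0)
    keep = np.flatnonzero(gap_frac <= max_gap_fraction)
    new_seqs = [mat[i, keep].tobytes().decode("ascii") for i in range(aln.n_taxa)]
    return LocusAlignment(aln.locus_id, list(aln.taxa), new_seqs), keep


def ambiguity_screen(
    aln: LocusAlignment,
    max_ambiguous_fraction: float = 0.03,
    count_missing: bool = False,
) -> tuple[list[str], list[str]]:
    """Partition taxa into (kept, flagged) by their ambiguous-base fraction.

    A taxon is flagged iff its fraction of IUPAC ambiguity codes among called
    (non-gap) positions *strictly* exceeds the threshold — an excess of
    ambiguous calls in a consensus sequence suggests collapsed paralogs.
    ``count_missing=True`` additionally counts N/? as ambiguous.
    """
    if not 0.0 <= max_ambiguous_fraction <= 1.0:
        raise ValueError("max_ambiguous_fraction must be in [0, 1]")
    ambig = AMBIGUITY_CODES | (MISSING_CHARS if count_missing else frozenset())
    kept, flagged = [], []
    for taxon, seq in zip(aln.taxa, aln.sequences):
        non_gap = sum(1 for c in seq if c not in GAP_CHARS)
        n_ambig = sum(1 for c in seq if c in ambig)
        frac = n_ambig / non_gap if non_gap else 0.0
        (flagged if frac > max_ambiguous_fraction else kept).append(taxon)
    return kept, flagged


def orf_stop_screen(
    coding_aln: LocusAlignment, frame: int = 0
) -> tuple[list[str], dict[str, list[int]]]:
    """Exclude taxa whose reading frame contains a premature stop codon.

    A taxon is excluded iff any complete in-frame codon *before the final
    codon* is TAA/TAG/TGA (standard code); codons containing gaps, missing
    data or ambiguity codes are skipped. Stop positions are reported 1-based
    in codon units. A terminal stop codon is allowed.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    if coding_aln.length - frame < 3:
        raise AlignmentShapeError("alignment shorter than one codon after frame offset")
    kept: list[str] = []
    excluded: dict[str, list[int]] = {}
    n_codons = (coding_aln.length - frame) // 3
    for taxon, seq in zip(coding_aln.taxa, coding_aln.sequences):
        stops = []
        for ci in range(n_codons - 1):  # final codon exempt
            codon = seq[frame + 3 * ci : frame + 3 * ci + 3].upper()
            if any(c not in "ACGT" for c in codon):
                continue
            if codon in STOP_CODONS:
                stops.append(ci + 1)
        if stops:
            excluded[taxon] = stops
        else:
            kept.append(taxon)
    return kept, excluded


# ---------------------------------------------------------------------------
# Phased haplotypes


@dataclass
class IndividualHaplotypes:
    """Bioinformatically phased alleles: two sequences per locus per individual."""

    individual_id: str
    phases: dict[str, tuple[str | None, str | None]]  # locus_id -> (phase A, phase B)

    def __post_init__(self) -> None:
        for locus, (a, b) in self.phases.items():
            if a is not None and b is not None and len(a) != len(b):
                raise AlignmentShapeError(
                    f"{self.individual_id}/{locus}: phases differ in length"
                )


def _stable_seed(seed: int, *tokens: str) -> list[int]:
    # crc32 is stable across runs/platforms, unlike hash()
    return [int(seed) & 0x7FFFFFFF] + [zlib.crc32(t.encode()) for t in tokens]


def choose_allele(
    h: IndividualHaplotypes, locus_id: str, seed: int
) -> tuple[str, str]:
    """Pick phase A or B uniformly at random for one individual and locus.

    Deterministic given ``seed`` (the draw is keyed on the individual and
    locus ids, so one global seed yields independent choices per pair).
    Returns ``(phase_label, sequence)``. If a phase is missing the present
    one is returned with a warning.
    """
    import warnings

    a, b = h.phases[locus_id]
    if a is None or b is None:
        warnings.warn(
            f"{h.individual_id}/{locus_id}: only one phase present; using it",
            stacklevel=2,
        )
        return ("A", a) if a is not None else ("B", b)
    rng = np.random.default_rng(_stable_seed(seed, h.individual_id, locus_id))
    return ("A", a) if rng.random() < 0.5 else ("B", b)


def collapse_phased_alignment(aln: LocusAlignment, seed: int) -> LocusAlignment:
    """Collapse ``id_A``/``id_B`` phased rows to one random allele per individual.

    Rows without the ``_A``/``_B`` suffix pass through unchanged. The random
    choice per (individual, locus) is deterministic given ``seed``.
    """
    by_ind: dict[str, dict[str, str]] = {}
    order: list[str] = []
    plain: dict[str, str] = {}
    for taxon, seq in zip(aln.taxa, aln.sequences):
        if taxon.endswith(("_A", "_B")):
            ind, phase = taxon[:-2], taxon[-1]
            by_ind.setdefault(ind, {})[phase] = seq
            if ind not in order:
                order.append(ind)
        else:
            plain[taxon] = seq
            if taxon not in order:
                order.append(taxon)
    taxa, seqs = [], []
    for ind in order:
        if ind in plain:
            taxa.append(ind)
            seqs.append(plain[ind])
        else:
            phases = by_ind[ind]
            h = IndividualHaplotypes(
                ind, {aln.locus_id: (phases.get("A"), phases.get("B"))}
            )
            _, seq = choose_allele(h, aln.locus_id, seed)
            taxa.append(ind)
            seqs.append(seq)
    return LocusAlignment(aln.locus_id, taxa, seqs)
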