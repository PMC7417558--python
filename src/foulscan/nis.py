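"""COI translation validation and non-indigenous species (NIS) screening.

COI is protein-coding, so genuine barcodes translate without internal stop
codons in at least one reading frame under a plausible genetic code;
nuclear mitochondrial pseudogenes (NUMTs) and other artefacts typically do
not.  Candidate OTUs whose species-level assignment appears on one or more
local invasive-species checklists are reported only if their sequence
passes this translation check.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "TranslationResult",
    "ChecklistEntry",
    "NisRecord",
    "DEFAULT_GENETIC_CODES",
    "translate_frames",
    "orf_validate",
    "match_checklist",
    "normalize_species",
]

#: Standard code plus the mitochondrial tables most relevant to marine
#: metazoan COI barcodes (vertebrate, mold/protozoan, invertebrate,
#: echinoderm/flatworm mitochondrial).
DEFAULT_GENETIC_CODES = (1, 2, 4, 5, 9)

FRAMES = (1, 2, 3, -1, -2, -3)

_IUPAC_DNA = set("ACGTRYSWKMBDHVN")
_UNAMBIG = set("ACGT")

#: Minimum fraction of codons covered by the longest stop-free stretch for
#: a translation to count as valid; tolerates amplicons starting mid-codon.
MIN_STOP_FREE_FRACTION = 0.90


@dataclass(frozen=True)
class TranslationResult:
    frame: int  # one of +-1, +-2, +-3
    genetic_code_id: int
    protein: str
    has_internal_stop: bool


@dataclass(frozen=True)
class ChecklistEntry:
    species: str  # case-normalized binomial
    source_tag: str


@dataclass
class NisRecord:
    otu_id: str
    species: str
    source_tags: set
    translation_ok: bool
    evidence: dict = field(default_factory=dict)
    frame: Optional[int] = None
    genetic_code_id: Optional[int] = None


def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _IUPAC_DNA
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    return seq


def _translate(frame_seq: str, code_id: int) -> str:
    table = CodonTable.unambiguous_dna_by_id[code_id]
    stops = set(table.stop_codons)
    fwd = table.forward_table
    protein = []
    for i in range(0, len(frame_seq) - len(frame_seq) % 3, 3):
        codon = frame_seq[i : i + 3]
        if set(codon) - _UNAMBIG:
            protein.append("X")  # ambiguity codes never count as stops
        elif codon in stops:
            protein.append("*")
        else:
            protein.append(fwd[codon])
    return "".join(protein)


def translate_frames(
    seq: str, codes: Sequence[int] = DEFAULT_GENETIC_CODES
) -> list:
    """Translate all six frames under each genetic code.

    Results are ordered frame-major (+1, +2, +3, -1, -2, -3), codes in the
    given order within each frame.  Trailing partial codons are ignored;
    ``has_internal_stop`` refers to stops before the final codon.
    """
    if not codes:
        raise ValueError("codes must be non-empty")
    seq = _check_sequence(seq)
    rc = str(Seq(seq).reverse_complement())
    out = []
    for frame in FRAMES:
        s = seq if frame > 0 else rc
        sub = s[abs(frame) - 1 :]
        for code in codes:
            protein = _translate(sub, code)
            out.append(
                TranslationResult(
                    frame=frame,
                    genetic_code_id=code,
                    protein=protein,
                    has_internal_stop="*" in protein[:-1],
                )
            )
    return out


def _longest_stop_free_run(protein: str) -> int:
    return max((len(r) for r in protein.split("*")), default=0)


def _passes(result: TranslationResult) -> bool:
    n = len(result.protein)
    if n == 0:
        return False
    return _longest_stop_free_run(result.protein) >= MIN_STOP_FREE_FRACTION * n


def orf_validate(seq: str, codes: Sequence[int] = DEFAULT_GENETIC_CODES):
    """Check that some (frame, code) yields a near-stop-free translation.

    Returns ``(passed, best)`` where ``best`` is the first passing
    translation in frame order +1, +2, +3, -1, -2, -3 (codes in given
    order within a frame), or None when every translation fails.
    """
    for result in translate_frames(seq, codes):
        if _passes(result):
            return True, result
    return False, None


def normalize_species(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip()).lower()


def match_checklist(
    assignments: Iterable,
    checklist: Sequence[ChecklistEntry],
    sequences: Mapping[str, str],
    codes: Sequence[int] = DEFAULT_GENETIC_CODES,
    synonyms: Optional[Mapping[str, str]] = None,
) -> list:
    """Screen species-level assignments against NIS checklists.

    A record is emitted iff the OTU has an ``assigned_*`` status, its
    species matches a checklist binomial (case-insensitively, after
    optional synonym mapping), and its sequence passes translation
    validation.  ``source_tags`` aggregates every checklist containing the
    species.  Output is sorted by otu_id, independent of input order.
    """
    by_species: dict = {}
    for entry in checklist:
        by_species.setdefault(normalize_species(entry.species), set()).add(
            entry.source_tag
        )
    synonyms = {
        normalize_species(k): normalize_species(v) for k, v in (synonyms or {}).items()
    }

    records = []
    for a in assignments:
        if not a.status.startswith("assigned") or a.species is None:
            continue
        species = normalize_species(a.species)
        species = synonyms.get(species, species)
        if species not in by_species:
            continue
        seq = sequences.get(a.otu_id)
        if seq is None:
            warnings.warn(
                f"{a.otu_id}: no sequence available for NIS candidate "
                f"{a.species!r}; excluded"
            )
            continue
        ok, best = orf_validate(seq, codes)
        if not ok:
            continue
        winner = a.evidence[0] if a.evidence else None
        records.append(
            NisRecord(
                otu_id=a.otu_id,
                species=species,
                source_tags=set(by_species[species]),
                translation_ok=True,
                evidence={
                    "sseqid": getattr(winner, "sseqid", None),
                    "pident": getattr(winner, "pident", None),
                    "evalue": getattr(winner, "evalue", None),
                },
                frame=best.frame,
                genetic_code_id=best.genetic_code_id,
            )
        )
    records.sort(key=lambda r: r.otu_id)
    return records
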