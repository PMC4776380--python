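"""Candidate-effector classification and related sequence-level reports.

The central rule: a transcript upregulated in head tissue whose protein
is predicted to be secreted (signal peptide present, no transmembrane
domain) encodes a *putative effector*; a body-upregulated secreted
transcript encodes an *other secreted* protein.  Salivary-gland
proteins are enriched in insect heads, which is what makes the
head-vs-body contrast an effector sieve.

Also here: ORF-completeness classification (start/stop codon presence),
overlap of saliva proteomics identifications with the predicted
effector sets, and tandem repeat-motif counting for repeat-bearing
effectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .expression import DECall
from .io_formats import AnnotationRecord

__all__ = [
    "EffectorCall",
    "OrfCompleteness",
    "OverlapSummary",
    "call_effectors",
    "classify_orf_completeness",
    "orf_flags_from_cds",
    "proteomics_overlap",
    "count_repeat_motifs",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}

_NO_ANNOTATION = AnnotationRecord(
    id="", has_signal_peptide=False, has_tm_domain=False, has_nls=False,
    best_db_hit_evalue=None, has_pfamA=False,
)


@dataclass
class EffectorCall:
    id: str
    category: str  # putative_effector | other_secreted | none
    nls_flag: bool
    dataset: str = ""


@dataclass
class OrfCompleteness:
    id: str
    orf_class: str  # complete | five_prime_partial | three_prime_partial | internal


@dataclass
class OverlapSummary:
    """Overlap between saliva proteomics ids and predicted effector sets."""

    total: int
    secreted: int  # signal peptide and no TM domain
    in_effector_set: int
    unmatched: list[str]
    secreted_ids: list[str]
    overlap_ids: list[str]


def call_effectors(
    de_calls: Sequence[DECall],
    annotations: Mapping[str, AnnotationRecord],
    dataset_of: Mapping[str, str] | None = None,
) -> list[EffectorCall]:
    """Apply the secretion x direction classification rule to DE calls.

    head_up + signal peptide + no TM -> putative_effector;
    body_up + signal peptide + no TM -> other_secreted; anything else
    (including secreted-but-TM) -> none.  The NLS flag is copied onto
    secreted calls.  Ids missing from the annotations are treated as
    all-flags-no, with a warning.
    """
    out: list[EffectorCall] = []
    missing = 0
    for call in de_calls:
        ann = annotations.get(call.id)
        if ann is None:
            ann = _NO_ANNOTATION
            missing += 1
        secreted = ann.has_signal_peptide and not ann.has_tm_domain
        if call.direction == "head_up" and secreted:
            category = "putative_effector"
        elif call.direction == "body_up" and secreted:
            category = "other_secreted"
        else:
            category = "none"
        out.append(
            EffectorCall(
                id=call.id,
                category=category,
                nls_flag=ann.has_nls if category != "none" else False,
                dataset=dataset_of.get(call.id, "") if dataset_of else "",
            )
        )
    if missing:
        warnings.warn(f"{missing} DE ids had no annotation record; treated as unannotated")
    return out


def classify_orf_completeness(sid: str, has_start_codon: bool, has_stop_codon: bool) -> OrfCompleteness:
    """Start+stop -> complete; no start -> 5'-partial; no stop -> 3'-partial; neither -> internal."""
    if has_start_codon and has_stop_codon:
        cls = "complete"
    elif has_stop_codon:
        cls = "five_prime_partial"
    elif has_start_codon:
        cls = "three_prime_partial"
    else:
        cls = "internal"
    return OrfCompleteness(id=sid, orf_class=cls)


def orf_flags_from_cds(cds: str) -> tuple[bool, bool]:
    """(has leading ATG, has trailing stop codon) for a CDS string."""
    cds = cds.upper()
    return cds.startswith("ATG"), len(cds) >= 3 and cds[-3:] in STOP_CODONS


def proteomics_overlap(
    saliva_ids: Iterable[str],
    effector_calls: Sequence[EffectorCall],
    annotations: Mapping[str, AnnotationRecord],
) -> OverlapSummary:
    """How many saliva-identified proteins are secreted / called effectors."""
    effector_set = {c.id for c in effector_calls if c.category == "putative_effector"}
    unmatched: list[str] = []
    secreted_ids: list[str] = []
    overlap_ids: list[str] = []
    total = 0
    for sid in sorted(set(saliva_ids)):
        total += 1
        ann = annotations.get(sid)
        if ann is None:
            unmatched.append(sid)
            continue
        if ann.has_signal_peptide and not ann.has_tm_domain:
            secreted_ids.append(sid)
            if sid in effector_set:
                overlap_ids.append(sid)
    return OverlapSummary(
        total=total,
        secreted=len(secreted_ids),
        in_effector_set=len(overlap_ids),
        unmatched=unmatched,
        secreted_ids=secreted_ids,
        overlap_ids=overlap_ids,
    )


def count_repeat_motifs(
    protein: str,
    motif: str,
    max_mismatch: int = 0,
    *,
    allow_overlap: bool = False,
) -> tuple[int, list[tuple[int, int]], int]:
    """Count repeat-motif occurrences in a protein sequence.

    Matches are found greedily left to right, non-overlapping by
    default, allowing up to ``max_mismatch`` substitutions per
    occurrence.  Returns (count, 0-based half-open spans, longest run
    of back-to-back matches).  Tandem-repeat effectors such as C002
    carry 2-6 copies of a 7-residue motif whose copy number matters for
    virulence, hence the explicit run length.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if len(motif) < 3:
        raise ValueError("motif length must be >= 3")
    if max_mismatch >= len(motif):
        raise ValueError("max_mismatch must be smaller than the motif length")
    m = len(motif)
    spans: list[tuple[int, int]] = []
    i = 0
    while i + m <= len(protein):
        window = protein[i : i + m]
        mismatches = sum(1 for a, b in zip(window, motif) if a != b)
        if mismatches <= max_mismatch:
            spans.append((i, i + m))
            i += 1 if allow_overlap else m
        else:
            i += 1
    max_run = run = 0
    prev_end = None
    for start, end in spans:
        run = run + 1 if prev_end == start else 1
        max_run = max(max_run, run)
        prev_end = end
    return len(spans), spans, max_run
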