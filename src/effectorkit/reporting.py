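"""Summary tables, percentage reports and the pipeline configuration.

All percentages are rounded half-away-from-zero, the convention
consistent with every printed percentage the pipeline reproduces
(e.g. 49/430 -> 11.4%, 3/390 -> 0.8%, 4590/28542 -> 16%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .effectors import EffectorCall, OrfCompleteness
from .expression import DECall

__all__ = [
    "PipelineConfig",
    "ReportRow",
    "round_half_away",
    "percent_report",
    "repertoire_summary",
    "completeness_report",
    "stability_report",
]


@dataclass
class PipelineConfig:
    """Every numeric threshold the pipeline applies, in one place.

    Defaults are the pipeline's operating point: raw p < 0.001 for
    differential expression; similarity edges kept at e-value <= 1e-35
    and clustered at MCL inflation 6; RBBH at 70% identity and 50%
    query coverage; core clusters need representation in 5 of the 8
    aphid datasets; pioneers require no database hit at 1e-5.
    """

    alpha: float = 0.001
    evalue_threshold: float = 1e-35
    inflation: float = 6.0
    rbbh_min_identity: float = 70.0
    rbbh_min_coverage: float = 50.0
    core_min_datasets: int = 5
    total_aphid_datasets: int = 8
    pioneer_db_evalue: float = 1e-5
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Flat key=value config file; unknown keys are errors."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs: dict = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
                key, val = (s.strip() for s in line.split("=", 1))
                if key not in known:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                kwargs[key] = int(val) if key in ("core_min_datasets", "total_aphid_datasets", "seed") else float(val)
        return cls(**kwargs)


@dataclass
class ReportRow:
    label: str
    numerator: int
    denominator: int
    percent: float


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (5 always rounds up in magnitude)."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def percent_report(numerator: int, denominator: int, decimals: int = 1, label: str = "") -> ReportRow:
    """Percentage of numerator over denominator at the stated precision."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    pct = round_half_away(100.0 * numerator / denominator, decimals)
    if decimals == 0:
        pct = float(int(pct))
    return ReportRow(label=label, numerator=numerator, denominator=denominator, percent=pct)


def repertoire_summary(
    effector_calls: Sequence[EffectorCall], de_calls: Sequence[DECall]
) -> pd.DataFrame:
    """Per-dataset counts of head/body upregulated, secreted, and NLS calls.

    Columns mirror the per-dataset repertoire table: upregulated head,
    secreted (head-up and secreted), secreted with NLS, and the same
    three for body tissue.
    """
    direction = {c.id: c.direction for c in de_calls}
    rows: dict[str, dict[str, int]] = {}
    cols = [
        "upregulated_head", "secreted_head", "secreted_head_nls",
        "upregulated_body", "secreted_body", "secreted_body_nls",
    ]
    for call in effector_calls:
        d = rows.setdefault(call.dataset or "all", dict.fromkeys(cols, 0))
        dirn = direction.get(call.id, "ns")
        if dirn == "head_up":
            d["upregulated_head"] += 1
            if call.category == "putative_effector":
                d["secreted_head"] += 1
                if call.nls_flag:
                    d["secreted_head_nls"] += 1
        elif dirn == "body_up":
            d["upregulated_body"] += 1
            if call.category == "other_secreted":
                d["secreted_body"] += 1
                if call.nls_flag:
                    d["secreted_body_nls"] += 1
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols).sort_index()


def completeness_report(classes: Sequence[OrfCompleteness]) -> pd.DataFrame:
    """Counts and nearest-integer percents per ORF-completeness class."""
    if not classes:
        raise ValueError("no ORF classes supplied")
    order = ["complete", "five_prime_partial", "three_prime_partial", "internal"]
    counts = {k: 0 for k in order}
    for c in classes:
        counts[c.orf_class] += 1
    total = len(classes)
    return pd.DataFrame(
        {
            "count": [counts[k] for k in order],
            "percent": [int(percent_report(counts[k], total, 0).percent) for k in order],
        },
        index=pd.Index(order, name="orf_class"),
    )


def stability_report(
    reference_ids: Iterable[str], de_calls: Sequence[DECall]
) -> dict[str, int]:
    """Housekeeping-style stability check: how many reference transcripts
    (genes expected to be constitutively expressed) are flagged as DE.

    Returns total / differentially-expressed / stable counts; a healthy
    pipeline leaves the vast majority of reference transcripts stable.
    """
    refs = set(reference_ids)
    direction = {c.id: c.direction for c in de_calls}
    n_de = sum(1 for r in refs if direction.get(r, "ns") != "ns")
    return {"total": len(refs), "differentially_expressed": n_de, "stable": len(refs) - n_de}
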