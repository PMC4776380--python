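"""Pairwise Nei-Gojobori (1986) dN/dS and the positive-selection screen.

The screen asks, for each orthologue group that contains a candidate
effector, whether the ratio of nonsynonymous substitutions per
nonsynonymous site to synonymous substitutions per synonymous site
(omega = dN/dS) exceeds 1 -- the classic signature of positive
selection.  The estimator is the original NG86 counting method:

* potential sites: for each codon, the expected fraction of one-step
  mutations that are synonymous, summed over the three positions and
  averaged over the two sequences (mutations to stop codons count as
  nonsynonymous, so S + N = 3 per codon);
* observed differences: codon pairs differing at k positions are
  resolved by averaging the synonymous/nonsynonymous step counts over
  all k! minimal mutational pathways with equal weights, excluding
  pathways that pass through a stop codon (if every pathway is blocked,
  all pathways are used);
* distances: the proportions pN = Nd/N and pS = Sd/S are corrected with
  the Jukes-Cantor formula d = -(3/4) ln(1 - 4p/3).

omega is defined only when dS > 0; groups aggregate pairwise omegas by
their median.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable

__all__ = [
    "CodonAlignment",
    "NG86Pair",
    "SelectionResult",
    "SaturationError",
    "back_translate",
    "trim_codon_alignment",
    "ng86",
    "screen_groups",
    "codon_sites",
    "pathway_differences",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS = set(_TABLE.stop_codons)
for _stop in STOP_CODONS:
    GENETIC_CODE[_stop] = "*"
_NTS = "ACGT"


class SaturationError(ValueError):
    """Raised when a difference proportion reaches the Jukes-Cantor limit (p >= 3/4)."""


@dataclass
class CodonAlignment:
    """Aligned CDS rows (gap '-'), column count divisible by 3."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths {sorted(lengths)}")
        if lengths and next(iter(lengths)) % 3 != 0:
            raise ValueError("alignment length is not a multiple of 3")

    @property
    def n_codons(self) -> int:
        if not self.rows:
            return 0
        return len(next(iter(self.rows.values()))) // 3

    def codons(self, sid: str) -> list[str]:
        s = self.rows[sid]
        return [s[i : i + 3] for i in range(0, len(s), 3)]


@dataclass
class NG86Pair:
    """NG86 estimates for one sequence pair."""

    id_a: str
    id_b: str
    dn: float
    ds: float
    omega: float | None
    n_codons: int
    sites_s: float = 0.0
    sites_n: float = 0.0
    diffs_s: float = 0.0
    diffs_n: float = 0.0


@dataclass
class SelectionResult:
    """Per-group selection screen outcome."""

    group_id: str
    pairs: list[NG86Pair]
    omega_aggregate: float | None  # median of defined pairwise omegas
    positive_selection: bool
    n_codons: int
    note: str = ""


def back_translate(
    protein_alignment: Mapping[str, str], cds_by_id: Mapping[str, str]
) -> CodonAlignment:
    """Project a protein alignment onto its coding sequences codon-by-codon.

    Each amino-acid column becomes one codon column; protein gaps become
    ``---``.  The ungapped protein must translate exactly from its CDS
    under the standard genetic code (a trailing stop codon on the CDS is
    tolerated and dropped).
    """
    rows: dict[str, str] = {}
    for sid, aligned in protein_alignment.items():
        if sid not in cds_by_id:
            raise ValueError(f"{sid}: no CDS supplied")
        cds = cds_by_id[sid].upper()
        if len(cds) >= 3 and cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        prot = aligned.replace("-", "")
        if len(cds) != 3 * len(prot):
            raise ValueError(
                f"{sid}: CDS length {len(cds)} is not 3 x ungapped protein length {len(prot)}"
            )
        out = []
        k = 0
        for pos, aa in enumerate(aligned):
            if aa == "-":
                out.append("---")
                continue
            codon = cds[3 * k : 3 * k + 3]
            trans = GENETIC_CODE.get(codon)
            if trans is None:
                raise ValueError(f"{sid}: ambiguous codon {codon!r} at codon {k + 1}")
            if trans != aa.upper():
                raise ValueError(
                    f"{sid}: codon {codon} translates to {trans}, alignment has {aa} "
                    f"at alignment column {pos + 1}"
                )
            out.append(codon)
            k += 1
        rows[sid] = "".join(out)
    return CodonAlignment(rows=rows)


def trim_codon_alignment(
    aln: CodonAlignment,
    drop_gap_columns: bool = True,
    mask_regions: Sequence[tuple[int, int]] = (),
) -> CodonAlignment:
    """Remove masked codon regions, then every codon column containing a gap.

    ``mask_regions`` are 1-based inclusive codon coordinates (e.g. the
    hypervariable N-terminal repeat region of an effector removed before
    dN/dS estimation).
    """
    n = aln.n_codons
    masked = set()
    for start, end in mask_regions:
        if start < 1 or end > n or start > end:
            raise ValueError(f"mask region ({start}, {end}) out of bounds for {n} codons")
        masked.update(range(start - 1, end))
    keep = [i for i in range(n) if i not in masked]
    cods = {sid: [aln.codons(sid)[i] for i in keep] for sid in aln.rows}
    if drop_gap_columns:
        ids = list(cods)
        n_left = len(keep)
        gapless = [
            j for j in range(n_left) if all("-" not in cods[sid][j] for sid in ids)
        ]
        cods = {sid: [cods[sid][j] for j in gapless] for sid in ids}
    return CodonAlignment(rows={sid: "".join(c) for sid, c in cods.items()})


def codon_sites(codon: str) -> tuple[float, float]:
    """Potential (synonymous, nonsynonymous) site counts for one codon.

    Each of the three positions contributes the fraction of its three
    possible single-nucleotide changes that are synonymous; changes to
    stop codons count as nonsynonymous, so the two counts always sum
    to 3.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    aa = GENETIC_CODE[codon]
    syn = 0.0
    for pos in range(3):
        for nt in _NTS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt not in STOP_CODONS and GENETIC_CODE[alt] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _pathways(codon_a: str, codon_b: str) -> list[list[tuple[str, str]]]:
    """All minimal mutational pathways a -> b as lists of codon steps."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        steps = []
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            steps.append((cur, nxt))
            cur = nxt
        paths.append(steps)
    return paths


def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Observed (synonymous, nonsynonymous) differences for a codon pair.

    Averaged with equal weights over all minimal pathways that avoid
    intermediate stop codons; if no pathway avoids them, all pathways
    are used.  Results are memoised, since long alignments revisit the
    same codon pairs constantly.
    """
    key = (codon_a, codon_b)
    cached = _PATH_CACHE.get(key)
    if cached is not None:
        return cached
    if codon_a in STOP_CODONS or codon_b in STOP_CODONS:
        raise ValueError(f"stop codon in pair ({codon_a}, {codon_b})")
    paths = _pathways(codon_a, codon_b)
    # intermediates are the landing codons of all but the final step
    valid = [p for p in paths if all(mid not in STOP_CODONS for _, mid in p[:-1])]
    if not valid:
        valid = paths
    syn = nonsyn = 0.0
    for p in valid:
        for frm, to in p:
            if GENETIC_CODE[frm] == GENETIC_CODE[to]:
                syn += 1
            else:
                nonsyn += 1
    k = len(valid)
    result = (syn / k, nonsyn / k) if k else (0.0, 0.0)
    _PATH_CACHE[key] = result
    return result


_PATH_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"difference proportion {p:.4f} >= 3/4; distance saturated")
    if p <= 0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86(cds_a: str, cds_b: str, *, id_a: str = "a", id_b: str = "b") -> NG86Pair:
    """Pairwise NG86 dN, dS and omega for two gap-free, stop-free CDS.

    Sequences must have equal length, a multiple of 3 (run after
    trimming).  omega is None when dS = 0.
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) % 3 != 0:
        raise ValueError("sequence length is not a multiple of 3")
    if "-" in a or "-" in b:
        raise ValueError("gaps present; trim the alignment before NG86")
    n_codons = len(a) // 3
    S = N = Sd = Nd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError(f"internal stop codon at codon {i // 3 + 1}")
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        if ca != cb:
            sd, nd = pathway_differences(ca, cb)
            Sd += sd
            Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    dn = _jukes_cantor(pn)
    if ps >= 0.75 and Nd == 0:
        # wholly synonymous divergence beyond the JC limit (short
        # sequences): the synonymous distance is unbounded but omega
        # is unambiguously 0
        ds, omega = math.inf, 0.0
    else:
        ds = _jukes_cantor(ps)
        omega = dn / ds if ds > 0 else None
    return NG86Pair(
        id_a=id_a, id_b=id_b, dn=dn, ds=ds, omega=omega, n_codons=n_codons,
        sites_s=S, sites_n=N, diffs_s=Sd, diffs_n=Nd,
    )


def screen_groups(
    groups: Mapping[str, Iterable[str]],
    codon_alignments: Mapping[str, CodonAlignment],
    effector_groups: set[str] | None = None,
    *,
    flag_ds_zero: bool = False,
) -> tuple[list[SelectionResult], dict]:
    """NG86 screen over orthologue groups; flag those with median omega > 1.

    Parameters
    ----------
    groups
        group id -> member sequence ids.
    codon_alignments
        group id -> trimmed codon alignment covering the members.
    effector_groups
        ids of groups containing a candidate effector; None screens all.
    flag_ds_zero
        when True, a group whose only signal is dN > 0 with dS = 0 in
        every pair (omega undefined but divergence wholly nonsynonymous)
        is also flagged.

    Returns the per-group results plus a summary dict with the counts
    and percentage used for reporting (groups with no defined pairwise
    omega are excluded from the percentage and reported separately).
    """
    results: list[SelectionResult] = []
    skipped: list[str] = []
    undefined: list[str] = []
    for gid, members in groups.items():
        if effector_groups is not None and gid not in effector_groups:
            continue
        members = list(members)
        if len(members) < 2:
            results.append(
                SelectionResult(gid, [], None, False, 0, note="skipped: fewer than 2 members")
            )
            skipped.append(gid)
            continue
        aln = codon_alignments[gid]
        pairs: list[NG86Pair] = []
        for id_a, id_b in itertools.combinations(members, 2):
            try:
                pairs.append(ng86(aln.rows[id_a], aln.rows[id_b], id_a=id_a, id_b=id_b))
            except SaturationError:
                continue
        omegas = sorted(p.omega for p in pairs if p.omega is not None)
        if omegas:
            mid = len(omegas) // 2
            agg = omegas[mid] if len(omegas) % 2 else 0.5 * (omegas[mid - 1] + omegas[mid])
            flagged = agg > 1.0
            note = ""
        else:
            agg = None
            ds_zero_divergent = any(p.ds == 0 and p.dn > 0 for p in pairs)
            flagged = bool(flag_ds_zero and ds_zero_divergent)
            note = "omega undefined (dS = 0 in all pairs)" if pairs else "no comparable pairs"
            undefined.append(gid)
        results.append(
            SelectionResult(
                gid, pairs, agg, flagged, aln.n_codons if pairs else 0, note=note
            )
        )
    screened = [r for r in results if r.omega_aggregate is not None]
    flagged = [r for r in screened if r.positive_selection]
    summary = {
        "n_groups": len(results),
        "n_screened": len(screened),
        "n_flagged": len(flagged),
        "percent_flagged": (100.0 * len(flagged) / len(screened)) if screened else None,
        "n_omega_undefined": len(undefined),
        "n_skipped_small": len(skipped),
    }
    return results, summary
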