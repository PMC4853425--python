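"""Disjoint-segment backbone-RMSD motif search over structure databases.

A query is an ordered list of backbone segments (the fullerene-binding
site is four helical segments donated by two chain pairs). The search
enumerates every combination of contiguous candidate runs in the target
— each query segment may land on any chain, in any assignment consistent
with the segment lengths, as long as placements do not overlap — and
keeps the combinations whose full-backbone (N, CA, C, O) least-squares
superposition RMSD is at or below the cutoff. The enumeration is
exhaustive over the searched database: correctness over speed, at desk
scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .geometry import BACKBONE_ATOMS, MotifQuery, Structure, pairwise_rmsd

AMINO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class MatchResult:
    """One placement of the query in a target structure."""

    target_id: str
    placements: list[tuple[str, int]]  # (chain, start residue) per query segment
    rmsd: float
    sequence: str


def one_letter(residue_name: str) -> str:
    return AMINO_ONE.get(residue_name.upper(), "X")


def _candidate_runs(structure: Structure, length: int):
    """Contiguous backbone-complete runs of `length` residues, per chain.

    Yields (chain, start_residue, coords (4*length, 3), sequence).
    """
    resmap = structure.residue_map()
    by_chain: dict[str, list[int]] = {}
    for chain, ri in resmap:
        by_chain.setdefault(chain, []).append(ri)
    for chain, indices in by_chain.items():
        indices = sorted(indices)
        for start in indices:
            window = list(range(start, start + length))
            coords = []
            seq = []
            ok = True
            for ri in window:
                residue = resmap.get((chain, ri))
                if residue is None or any(a not in residue for a in BACKBONE_ATOMS):
                    ok = False
                    break
                coords.extend(residue[a].position for a in BACKBONE_ATOMS)
                seq.append(one_letter(residue[BACKBONE_ATOMS[0]].residue_name))
            if ok:
                yield chain, start, np.array(coords), "".join(seq)


def _placements_overlap(p1: tuple[str, int], len1: int,
                        p2: tuple[str, int], len2: int) -> bool:
    if p1[0] != p2[0]:
        return False
    s1, e1 = p1[1], p1[1] + len1 - 1
    s2, e2 = p2[1], p2[1] + len2 - 1
    return s1 <= e2 and s2 <= e1


def search_motif(query: MotifQuery, database: list[tuple[str, Structure]],
                 rmsd_cutoff: float) -> list[MatchResult]:
    """Exhaustive disjoint-segment search of `query` against a database.

    `database` is a list of (target id, structure). Matches are returned
    sorted ascending by RMSD, ties broken by (target id, placements).
    Symmetric duplicate placements (the same set of segment runs matched
    in a different segment order, possible for repeated segment lengths)
    are collapsed to their best-RMSD representative.

    Placements are enumerated depth-first, segments in decreasing-length
    order, with an exact early-abort bound: the optimal RMSD over a subset
    of the atoms, scaled by sqrt(n_subset / n_total), can never exceed the
    full-motif optimal RMSD, so pruning on it discards no true match and
    the search remains provably exhaustive.
    """
    if query.atom_count == 0:
        raise InvalidInputError("query is empty")
    if not (rmsd_cutoff >= 0):
        raise InvalidParameterError("rmsd_cutoff must be non-negative")
    lengths = query.segment_lengths
    n_total = query.atom_count
    order = sorted(range(len(lengths)), key=lambda i: -lengths[i])
    q_parts = []
    pos = 0
    for n in lengths:
        q_parts.append(query.coordinates[pos:pos + 4 * n])
        pos += 4 * n
    matches: dict[tuple[str, tuple], MatchResult] = {}

    for target_id, structure in database:
        runs_by_length = {
            n: list(_candidate_runs(structure, n)) for n in set(lengths)
        }

        def dfs(depth: int, chosen: list, q_stack: np.ndarray | None,
                t_stack: np.ndarray | None) -> None:
            if depth == len(order):
                rmsd = pairwise_rmsd(q_stack, t_stack)
                if rmsd <= rmsd_cutoff:
                    by_seg = dict(zip(order, chosen))
                    combo = [by_seg[i] for i in range(len(lengths))]
                    placements = [(c[0], c[1]) for c in combo]
                    seq = "".join(c[3] for c in combo)
                    key = (target_id, _canonical_key(placements, lengths))
                    prev = matches.get(key)
                    if prev is None or rmsd < prev.rmsd:
                        matches[key] = MatchResult(target_id, placements, rmsd, seq)
                return
            seg = order[depth]
            for cand in runs_by_length[lengths[seg]]:
                clash = any(_placements_overlap(
                    (cand[0], cand[1]), lengths[seg],
                    (prev_c[0], prev_c[1]), lengths[order[k]])
                    for k, prev_c in enumerate(chosen))
                if clash:
                    continue
                nq = q_parts[seg] if q_stack is None else np.vstack([q_stack, q_parts[seg]])
                nt = cand[2] if t_stack is None else np.vstack([t_stack, cand[2]])
                partial = pairwise_rmsd(nq, nt)
                if partial * math.sqrt(len(nq) / n_total) > rmsd_cutoff:
                    continue
                dfs(depth + 1, chosen + [cand], nq, nt)

        dfs(0, [], None, None)

    return sorted(matches.values(),
                  key=lambda m: (m.rmsd, m.target_id, m.placements))


def _canonical_key(placements, lengths) -> tuple:
    """Order-independent key within groups of equal segment length."""
    groups: dict[int, list] = {}
    for p, n in zip(placements, lengths):
        groups.setdefault(n, []).append(p)
    return tuple((n, tuple(sorted(ps))) for n, ps in sorted(groups.items()))


def dedupe_matches(matches: list[MatchResult]) -> list[MatchResult]:
    """Keep only the lowest-RMSD match per distinct concatenated sequence."""
    best: dict[str, MatchResult] = {}
    for m in matches:
        prev = best.get(m.sequence)
        if prev is None or m.rmsd < prev.rmsd:
            best[m.sequence] = m
    keep = set(id(m) for m in best.values())
    return [m for m in matches if id(m) in keep]


@dataclass
class LogoTable:
    """Per-position amino-acid frequencies over contributing matches."""

    positions: list[int]                     # 1-based query residue positions
    frequencies: list[dict[str, float]]      # per position; {} when empty
    n_matches: int

    def frequency(self, position: int, aa: str) -> float:
        return self.frequencies[position - 1].get(aa, 0.0)


def build_logo(matches: list[MatchResult], rmsd_threshold: float = 0.3) -> LogoTable:
    """Position-specific residue frequencies from sub-threshold matches.

    Matches are deduplicated by sequence first; only those with
    rmsd <= rmsd_threshold contribute. Positions with no contributing
    match carry an empty frequency map.
    """
    contributing = [m for m in dedupe_matches(matches) if m.rmsd <= rmsd_threshold]
    if not contributing:
        return LogoTable(positions=[], frequencies=[], n_matches=0)
    length = len(contributing[0].sequence)
    if any(len(m.sequence) != length for m in contributing):
        raise InvalidInputError("matches have inconsistent sequence lengths")
    freqs: list[dict[str, float]] = []
    for pos in range(length):
        counts: dict[str, int] = {}
        for m in contributing:
            aa = m.sequence[pos]
            counts[aa] = counts.get(aa, 0) + 1
        total = sum(counts.values())
        freqs.append({aa: c / total for aa, c in counts.items()})
    return LogoTable(positions=list(range(1, length + 1)), frequencies=freqs,
                     n_matches=len(contributing))
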