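"""Independent brute-force oracles used to cross-check homology operations."""

from __future__ import annotations

from typing import Dict, Iterable, List, Set, Tuple


def best_hit_oracle(rows: Iterable[tuple]) -> Dict[str, str]:
    """Exhaustive per-query minimization over (query, subject, evalue, pident, aln_len).

    Sorts each query's full candidate list by the documented tie chain and
    takes the head — independent of the single-pass reduction it checks.
    """
    by_query: Dict[str, List[tuple]] = {}
    for q, s, e, p, l in rows:
        by_query.setdefault(q, []).append((q, s, e, p, l))
    out: Dict[str, str] = {}
    for q, cands in by_query.items():
        cands = sorted(cands, key=lambda r: (r[2], -r[3], -r[4], r[1]))
        out[q] = cands[0][1]
    return out


def bbh_oracle(
    forward: Dict[str, str], reverse: Dict[str, str]
) -> Set[Tuple[str, str]]:
    """Test reciprocity for every (x, y) in the full cross product."""
    pairs = set()
    for x in forward:
        for y in reverse:
            if forward[x] == y and reverse[y] == x:
                pairs.add((x, y))
    return pairs


def closure_oracle(pairs: Iterable[Tuple[str, str]]) -> List[frozenset]:
    """Transitive closure by repeated merging passes until a fixed point."""
    groups: List[set] = [set(p) for p in pairs]
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            if not groups[i]:
                continue
            for j in range(i + 1, len(groups)):
                if groups[j] and groups[i] & groups[j]:
                    groups[i] |= groups[j]
                    groups[j] = set()
                    changed = True
    return sorted(
        (frozenset(g) for g in groups if g), key=lambda g: sorted(g)[0]
    )
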