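"""Independent brute-force quadruplex matcher used as a test oracle.

Implements leftmost greedy matching of the tract/loop pattern family by
explicit recursive backtracking over the pattern elements — no regular
expressions — so it shares no code path with the scanner it checks.
"""

from __future__ import annotations

LOOP_ALPHABET = frozenset("ACGT")


def _match_end_at(seq: str, pos: int, base: str, min_tract: int,
                  n_tracts: int, max_loop: int) -> int | None:
    """End of the greedy match starting exactly at ``pos``, else None.

    Elements alternate tract, loop, tract, ..., tract (n_tracts tracts).
    Greedy semantics: each element tries its longest extent first and
    backtracks, exactly the search order of a backtracking regex engine.
    """
    n = len(seq)

    def run_length(p: int) -> int:
        q = p
        while q < n and seq[q] == base:
            q += 1
        return q - p

    def rec(p: int, element: int) -> int | None:
        # elements 0, 2, 4, ... are tracts; odd elements are loops
        if element == 2 * n_tracts - 1:
            return p
        if element % 2 == 0:
            r = run_length(p)
            for length in range(r, min_tract - 1, -1):
                end = rec(p + length, element + 1)
                if end is not None:
                    return end
            return None
        longest = 0
        while (
            longest < max_loop
            and p + longest < n
            and seq[p + longest] in LOOP_ALPHABET
        ):
            longest += 1
        for length in range(longest, -1, -1):
            end = rec(p + length, element + 1)
            if end is not None:
                return end
        return None

    return rec(pos, 0)


def oracle_scan(seq: str, base: str, min_tract: int, n_tracts: int,
                max_loop: int) -> list[tuple[int, int]]:
    """Leftmost greedy non-overlapping (start, end) matches."""
    seq = seq.upper()
    matches = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] != base:
            i += 1
            continue
        end = _match_end_at(seq, i, base, min_tract, n_tracts, max_loop)
        if end is None:
            i += 1
        else:
            matches.append((i, end))
            i = end
    return matches


def oracle_is_member(seq: str, base: str, min_tract: int, n_tracts: int,
                     max_loop: int) -> bool:
    """Whole-string membership in the pattern class (exhaustive check)."""
    end = _full_match(seq, 0, base, min_tract, n_tracts, max_loop)
    return end


def _full_match(seq, pos, base, min_tract, n_tracts, max_loop) -> bool:
    n = len(seq)

    def rec(p: int, element: int) -> bool:
        if element == 2 * n_tracts - 1:
            return p == n
        if element % 2 == 0:
            r = 0
            while p + r < n and seq[p + r] == base:
                r += 1
            return any(
                rec(p + length, element + 1)
                for length in range(min_tract, r + 1)
            )
        return any(
            rec(p + length, element + 1)
            for length in range(0, max_loop + 1)
            if p + length <= n
            and all(c in LOOP_ALPHABET for c in seq[p : p + length])
        )

    return rec(pos, 0)
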