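"""Independent alignment oracles for testing the production aligner.

Two tiers, both independent of the Biopython-backed implementation:

* :func:`enumerate_alignments_signatures` — true brute force: recursively
  enumerates every monotone alignment path (read fully aligned, free
  reference flanks) and scores it.  Exponential; only usable for reads of a
  handful of bases.  It exists to validate the second tier.

* :func:`gotoh_signatures` — a plain-Python three-state affine-gap dynamic
  program with the same semantics, returning the optimal score and the set of
  operation signatures achieved by optimal alignments.

An operation *signature* is ``(n_match, n_mismatch, sorted ins gap lengths,
sorted del gap lengths)`` — the multiset of operations without placement.

Scoring: match +1, mismatch -1, a gap of length k costs 4 + (k-1).
"""

from __future__ import annotations

from functools import lru_cache

NEG = float("-inf")
MATCH, MISMATCH = 1, -1
OPEN, EXTEND = 4, 1  # costs (positive)


def signature_of_ops(ops) -> tuple:
    """Signature of a pearkit Alignment.ops tuple."""
    n_match = sum(o.length for o in ops if o.op == "match")
    n_mis = sum(o.length for o in ops if o.op == "mismatch")
    ins = tuple(sorted(o.length for o in ops if o.op == "ins"))
    dele = tuple(sorted(o.length for o in ops if o.op == "del"))
    return (n_match, n_mis, ins, dele)


def _score_path(read: str, window: str, path: tuple[str, ...]) -> tuple:
    """Score an op-character path ('M' diagonal, 'I' read-only, 'D' ref-only)
    and build its signature."""
    i = j = 0
    score = 0
    n_match = n_mis = 0
    ins_lens: list[int] = []
    del_lens: list[int] = []
    prev = None
    for op in path:
        if op == "M":
            if read[i] == window[j]:
                score += MATCH
                n_match += 1
            else:
                score -= -MISMATCH
                n_mis += 1
            i += 1
            j += 1
        elif op == "I":
            if prev == "I":
                score -= EXTEND
                ins_lens[-1] += 1
            else:
                score -= OPEN
                ins_lens.append(1)
            i += 1
        else:  # D
            if prev == "D":
                score -= EXTEND
                del_lens[-1] += 1
            else:
                score -= OPEN
                del_lens.append(1)
            j += 1
        prev = op
    sig = (n_match, n_mis, tuple(sorted(ins_lens)), tuple(sorted(del_lens)))
    return score, sig


def enumerate_alignments_signatures(read: str, ref: str):
    """Brute-force optimum over every window of ``ref`` and every monotone
    path.  Returns (best score, set of optimal signatures)."""
    best = NEG
    sigs: set[tuple] = set()
    n = len(ref)

    def paths(li: int, lj: int):
        # all op strings consuming li read bases and lj window bases
        stack = [((), 0, 0)]
        while stack:
            path, i, j = stack.pop()
            if i == li and j == lj:
                yield path
                continue
            if i < li and j < lj:
                stack.append((path + ("M",), i + 1, j + 1))
            if i < li:
                stack.append((path + ("I",), i + 1, j))
            if j < lj:
                stack.append((path + ("D",), i, j + 1))

    for a in range(n + 1):
        for b in range(a, n + 1):
            window = ref[a:b]
            for path in paths(len(read), len(window)):
                # interior deletions only: a path starting or ending with D
                # is equivalent to a smaller window, already enumerated
                if path and (path[0] == "D" or path[-1] == "D"):
                    continue
                score, sig = _score_path(read, window, path)
                if score > best:
                    best = score
                    sigs = {sig}
                elif score == best:
                    sigs.add(sig)
    return best, sigs


def gotoh_signatures(read: str, ref: str):
    """Three-state affine DP with free reference flanks; returns
    (best score, set of optimal signatures)."""
    L, N = len(read), len(ref)

    # S[state][i][j]: best score of an alignment consuming read[:i] and ending
    # at reference position j in `state` (M diag, I read gap-in-ref, D ref
    # consumed).  Reference prefix ref[:j0] before the first op is free.
    M = [[NEG] * (N + 1) for _ in range(L + 1)]
    I = [[NEG] * (N + 1) for _ in range(L + 1)]
    D = [[NEG] * (N + 1) for _ in range(L + 1)]
    START = 0.0
    for j in range(N + 1):
        # empty prefix of the read at any reference offset, cost 0
        M[0][j] = START  # treated as "fresh start" state
    for i in range(1, L + 1):
        for j in range(N + 1):
            # I: read base i-1 unaligned (insertion)
            cand_open = max(M[i - 1][j], D[i - 1][j]) - OPEN
            cand_ext = I[i - 1][j] - EXTEND
            I[i][j] = max(cand_open, cand_ext)
            if j >= 1:
                diag = max(M[i - 1][j - 1], I[i - 1][j - 1], D[i - 1][j - 1])
                s = MATCH if read[i - 1] == ref[j - 1] else MISMATCH
                M[i][j] = diag + s
                # D: reference base j-1 skipped (deletion), interior only
                cand_open = max(M[i][j - 1], I[i][j - 1]) - OPEN
                cand_ext = D[i][j - 1] - EXTEND
                # forbid deletions before any read base is consumed
                if i == 0:
                    cand_open = cand_ext = NEG
                D[i][j] = max(cand_open, cand_ext)
    # trailing reference flank is free; trailing deletion never optimal but
    # also should not be counted: take M or I at i=L, any j
    best = NEG
    for j in range(N + 1):
        best = max(best, M[L][j], I[L][j])
    if L == 0:
        best = 0.0

    # enumerate optimal signatures by walking back along optimal transitions;
    # partials are (n_match, n_mismatch, closed ins lens, closed del lens,
    # open run length of the *current* state)
    def _close(partial: tuple, state: str) -> tuple:
        nm, nx, ci, cd, orl = partial
        if state == "I" and orl:
            ci = tuple(sorted(ci + (orl,)))
        elif state == "D" and orl:
            cd = tuple(sorted(cd + (orl,)))
        return nm, nx, ci, cd

    @lru_cache(maxsize=None)
    def back(state: str, i: int, j: int) -> frozenset:
        """Partial signatures of every optimal path prefix ending at
        (state, i, j)."""
        if i == 0:
            if state == "M":
                return frozenset({(0, 0, (), (), 0)})
            return frozenset()
        out = set()
        if state == "M":
            if j == 0 or M[i][j] == NEG:
                return frozenset()
            s = MATCH if read[i - 1] == ref[j - 1] else MISMATCH
            for st, val in (("M", M[i - 1][j - 1]), ("I", I[i - 1][j - 1]),
                            ("D", D[i - 1][j - 1])):
                if val > NEG and val + s == M[i][j]:
                    for p in back(st, i - 1, j - 1):
                        nm, nx, ci, cd = _close(p, st)
                        if s == MATCH:
                            out.add((nm + 1, nx, ci, cd, 0))
                        else:
                            out.add((nm, nx + 1, ci, cd, 0))
        elif state == "I":
            if I[i][j] == NEG:
                return frozenset()
            if I[i - 1][j] > NEG and I[i - 1][j] - EXTEND == I[i][j]:
                for nm, nx, ci, cd, orl in back("I", i - 1, j):
                    out.add((nm, nx, ci, cd, orl + 1))
            for st, val in (("M", M[i - 1][j]), ("D", D[i - 1][j])):
                if val > NEG and val - OPEN == I[i][j]:
                    for p in back(st, i - 1, j):
                        nm, nx, ci, cd = _close(p, st)
                        out.add((nm, nx, ci, cd, 1))
        else:  # D
            if j == 0 or D[i][j] == NEG:
                return frozenset()
            if D[i][j - 1] > NEG and D[i][j - 1] - EXTEND == D[i][j]:
                for nm, nx, ci, cd, orl in back("D", i, j - 1):
                    out.add((nm, nx, ci, cd, orl + 1))
            for st, val in (("M", M[i][j - 1]), ("I", I[i][j - 1])):
                if val > NEG and val - OPEN == D[i][j]:
                    for p in back(st, i, j - 1):
                        nm, nx, ci, cd = _close(p, st)
                        out.add((nm, nx, ci, cd, 1))
        return frozenset(out)

    sigs: set[tuple] = set()
    for j in range(N + 1):
        for state, table in (("M", M), ("I", I)):
            if table[L][j] == best:
                for p in back(state, L, j):
                    sigs.add(_close(p, state))
    back.cache_clear()
    return best, sigs
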