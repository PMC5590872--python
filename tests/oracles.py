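"""Independent reference implementations used only to cross-check results.

These deliberately take the slow, obvious route (full dynamic-programming
matrices, exhaustive enumeration) and share no code with the package paths
they verify.
"""

from __future__ import annotations

import itertools

NEG = -(10**9)


def affine_dp_score(sx: str, sy: str) -> int:
    """Full-matrix global affine alignment score: match +1, mismatch -1,
    gap -2/base with -2 extra to open; N never matches."""
    n, m = len(sx), len(sy)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    D = [[NEG] * (m + 1) for _ in range(n + 1)]
    I = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0
    for i in range(1, n + 1):
        D[i][0] = -4 - 2 * (i - 1)
    for j in range(1, m + 1):
        I[0][j] = -4 - 2 * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = 1 if (sx[i - 1] == sy[j - 1] and sx[i - 1] != "N") else -1
            M[i][j] = max(M[i - 1][j - 1], D[i - 1][j - 1], I[i - 1][j - 1]) + sub
            D[i][j] = max(M[i - 1][j] - 4, D[i - 1][j] - 2, I[i - 1][j] - 4)
            I[i][j] = max(M[i][j - 1] - 4, D[i][j - 1] - 4, I[i][j - 1] - 2)
    return max(M[n][m], D[n][m], I[n][m])


def polymorphic_windows(cols: str, max_exact_block: int) -> list[tuple[int, int]]:
    """Run-list route to the window rule: cut at M-runs >= max_exact_block,
    hand each window up to max_exact_block - 1 columns of its flanking
    separators (interior separators split floor/ceil between neighbours)."""
    e = max_exact_block - 1
    runs = []
    pos = 0
    for ch, grp in itertools.groupby(cols):
        ln = len(list(grp))
        runs.append((ch, pos, pos + ln))
        pos += ln
    seps = [(a, b) for ch, a, b in runs if ch == "M" and b - a >= max_exact_block]
    bounds = [0] + [x for s in seps for x in s] + [len(cols)]
    out = []
    for i in range(0, len(bounds), 2):
        a, b = bounds[i], bounds[i + 1]
        if a >= b or set(cols[a:b]) <= {"M"}:
            continue
        left = seps[i // 2 - 1] if i > 0 else None
        right = seps[i // 2] if i // 2 < len(seps) else None
        tl = 0
        if left is not None:
            r = left[1] - left[0]
            tl = min(e, r) if left[0] == 0 else min(e, r - r // 2)
        tr = 0
        if right is not None:
            r = right[1] - right[0]
            tr = min(e, r) if right[1] == len(cols) else min(e, r // 2)
        out.append((a - tl, b + tr))
    return out


def best_collinear_subset(anchors, max_gap: int):
    """Exhaustive max-score collinear subset over <= ~15 anchors."""
    n = len(anchors)
    best_score, best_set = -1, ()
    for mask in range(1, 1 << n):
        chosen = [anchors[i] for i in range(n) if mask >> i & 1]
        if len({a.strand for a in chosen}) > 1:
            continue
        chosen.sort(key=lambda a: a.x_pos)
        ok = True
        for p, q in zip(chosen, chosen[1:]):
            gx = q.x_pos - (p.x_pos + p.length)
            if p.strand.value == "+":
                gy = q.y_pos - (p.y_pos + p.length)
            else:
                gy = p.y_pos - (q.y_pos + q.length)
            if not (0 <= gx <= max_gap and 0 <= gy <= max_gap):
                ok = False
                break
        if ok:
            score = sum(a.length for a in chosen)
            if score > best_score:
                best_score, best_set = score, tuple(chosen)
    return best_score, best_set


def best_member_by_exhaustive_diagonals(
    read: str, members: list[tuple[int, str]], min_identity: float, span_frac: float
):
    """Best marker member for a read by scoring EVERY diagonal of every
    member (no seeding): gapless match +1 / mismatch -1 over the overlap.
    Returns (member_numbers_at_best, best_score) or ([], None)."""
    best = None
    winners: set[int] = set()
    lr = len(read)
    for number, seq in members:
        for oriented in (seq, _revcomp(seq)):
            lm = len(oriented)
            for diag in range(-(lr - 1), lm):
                r0 = max(0, -diag)
                r1 = min(lr, lm - diag)
                span = r1 - r0
                if span <= 0 or span + 1e-9 < span_frac * min(lr, lm):
                    continue
                matches = sum(
                    1
                    for t in range(r0, r1)
                    if read[t] == oriented[t + diag] and read[t] in "ACGT"
                )
                if matches + 1e-9 < min_identity * span:
                    continue
                score = 2 * matches - span
                if best is None or score > best:
                    best = score
                    winners = {number}
                elif score == best:
                    winners.add(number)
    return sorted(winners), best


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
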