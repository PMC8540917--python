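"""Independent reference implementations used only by the tests.

These are deliberately plain, non-incremental transcriptions (python
lists, ``math`` module, explicit loops) of the update recurrences,
excursion rule and tolerance matching, written separately from the
package so that agreement is a genuine cross-check rather than the same
code called twice.
"""

import math

VARIANCE_FLOOR = 1e-12


def reference_sdar_pass(x, k, r):
    """One SDAR scoring pass, literal recurrences, batch form.

    Returns (y, flagged): the per-step negative log Gaussian density of
    each sample under the previous step's model, with positions scored
    before k observations were seen — or while the variance estimate was
    still exactly zero — as flagged zeros.
    """
    n = len(x)
    y = [0.0] * n
    flagged = [True] * n
    mu = 0.0
    C = [0.0] * (k + 1)
    a = [0.0] * k
    sigma = 0.0
    hist = []
    for t in range(n):
        xt = x[t]
        ready = len(hist) >= k
        # prediction from the state as it stood before x_t
        if ready:
            xhat = mu
            for i in range(1, k + 1):
                xhat += a[i - 1] * (hist[-i] - mu)
        else:
            xhat = mu
        if ready and sigma > 0.0:
            v = sigma if sigma > VARIANCE_FLOOR else VARIANCE_FLOOR
            y[t] = 0.5 * math.log(2.0 * math.pi * v) + (xt - xhat) ** 2 / (2.0 * v)
            flagged[t] = False
        # updates
        if t == 0:
            mu = xt
            xhat = mu
        mu = (1.0 - r) * mu + r * xt
        for i in range(k + 1):
            if i == 0:
                lag = xt
            elif len(hist) >= i:
                lag = hist[-i]
            else:
                lag = mu
            C[i] = (1.0 - r) * C[i] + r * (xt - mu) * (lag - mu)
        a = reference_yule_walker(C, k)
        sigma = (1.0 - r) * sigma + r * (xt - xhat) ** 2
        hist.append(xt)
        if len(hist) > k:
            hist.pop(0)
    return y, flagged


def reference_yule_walker(C, k):
    """Solve C_i = sum_j a_j C_{i-j} (C_{-i} = C_i) by Gaussian elimination;
    singular systems give the zero vector."""
    if k == 1:
        return [C[1] / C[0]] if C[0] > 0 else [0.0]
    mat = [[C[abs(i - j)] for j in range(k)] for i in range(k)]
    rhs = list(C[1 : k + 1])
    aug = [row + [b] for row, b in zip(mat, rhs)]
    for col in range(k):
        piv = max(range(col, k), key=lambda i: abs(aug[i][col]))
        if abs(aug[piv][col]) < 1e-300:
            return [0.0] * k
        aug[col], aug[piv] = aug[piv], aug[col]
        for i in range(k):
            if i == col:
                continue
            f = aug[i][col] / aug[col][col]
            for j in range(col, k + 1):
                aug[i][j] -= f * aug[col][j]
    sol = [aug[i][k] / aug[i][i] for i in range(k)]
    if any(not math.isfinite(v) for v in sol):
        return [0.0] * k
    return sol


def reference_smooth(values, w):
    """Trailing mean over the last w values, prefix averaged over what exists."""
    out = []
    for t in range(len(values)):
        lo = max(0, t - w + 1)
        window = values[lo : t + 1]
        out.append(sum(window) / len(window))
    return out


def reference_change_score(x, k, r, w, w2):
    """Full two-stage change score: score, smooth(w), score again, smooth(w2)."""
    y1, f1 = reference_sdar_pass(list(x), k, r)
    s1 = reference_smooth(y1, w)
    y2, f2 = reference_sdar_pass(s1, k, r)
    s2 = reference_smooth(y2, w2)
    flagged = [a or b for a, b in zip(f1, f2)]
    return s2, flagged


def brute_force_poi(times, scores, gamma, burn_in):
    """Enumerate maximal strictly-above-gamma runs among post-burn-in
    samples; return ([(argmax_index, run_first, run_last)], n_o)."""
    n = len(scores)
    eligible = [i for i in range(n) if times[i] >= times[0] + burn_in]
    runs = []
    cur = []
    for i in eligible:
        if scores[i] > gamma:
            if cur and i == cur[-1] + 1:
                cur.append(i)
            else:
                if cur:
                    runs.append(cur)
                cur = [i]
        else:
            if cur:
                runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    out = []
    for run in runs:
        best = max(run, key=lambda i: (scores[i], -i))  # earliest tie wins
        out.append((best, run[0], run[-1]))
    n_o = sum(len(run) for run in runs)
    return out, n_o


def brute_force_match(cand_times, event_times, tolerance):
    """Exhaustive pairwise tolerance check."""
    n_c = 0
    for e in event_times:
        if any(abs(c - e) <= tolerance for c in cand_times):
            n_c += 1
    correct = sorted(
        {c for c in cand_times if any(abs(c - e) <= tolerance for e in event_times)}
    )
    return n_c, correct
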