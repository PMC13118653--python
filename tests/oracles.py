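"""Brute-force reference implementations used to validate the fast paths.

These deliberately use the most transparent formulation available —
explicit loops, full permutation enumeration, explicit design-matrix
projections — and share no code with the implementations they check.
"""

import itertools

import numpy as np


def permanova_brute(d: np.ndarray, labels) -> tuple:
    """Pseudo-F, R2 and the exact enumeration p-value over all label
    permutations (use only for small n)."""
    labels = np.asarray(labels)
    n = d.shape[0]

    def f_stat(lab):
        ss_t = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                ss_t += d[i, j] ** 2
        ss_t /= n
        ss_w = 0.0
        for g in np.unique(lab):
            idx = np.flatnonzero(lab == g)
            s = 0.0
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    s += d[idx[a], idx[b]] ** 2
            ss_w += s / len(idx)
        ss_b = ss_t - ss_w
        a = len(np.unique(lab))
        return (ss_b / (a - 1)) / (ss_w / (n - a)), ss_b / ss_t

    f_obs, r2 = f_stat(labels)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        f_p, _ = f_stat(labels[list(perm)])
        count += f_p >= f_obs - 1e-12
        total += 1
    return f_obs, r2, count / total


def dispersion_f_brute(distances, labels) -> float:
    """One-way ANOVA F on given per-sample distances-to-centroid."""
    distances = np.asarray(distances, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    grand = distances.mean()
    ssb = sum(
        (labels == g).sum() * (distances[labels == g].mean() - grand) ** 2 for g in groups
    )
    ssw = sum(((distances[labels == g] - distances[labels == g].mean()) ** 2).sum()
              for g in groups)
    return (ssb / (len(groups) - 1)) / (ssw / (len(distances) - len(groups)))


def anova2_partial_eta2_brute(y, a, b):
    """Type-II two-way ANOVA partial eta^2 via explicit projection matrices."""
    y = np.asarray(y, dtype=float)
    a = np.asarray(a)
    b = np.asarray(b)
    n = len(y)

    def dummies(f):
        levels = np.unique(f)
        return np.column_stack([(f == lv).astype(float) for lv in levels[1:]])

    one = np.ones((n, 1))
    A = dummies(a)
    B = dummies(b)
    AB = np.column_stack([A[:, i] * B[:, j] for i in range(A.shape[1]) for j in range(B.shape[1])])

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    full = np.column_stack([one, A, B, AB])
    rss_full = rss(full)
    # type II: each main effect adjusted for the other main effect (no interaction)
    ss_a = rss(np.column_stack([one, B])) - rss(np.column_stack([one, A, B]))
    ss_b = rss(np.column_stack([one, A])) - rss(np.column_stack([one, A, B]))
    ss_ab = rss(np.column_stack([one, A, B])) - rss_full
    return {
        "A": ss_a / (ss_a + rss_full),
        "B": ss_b / (ss_b + rss_full),
        "A:B": ss_ab / (ss_ab + rss_full),
    }


def mantel_r_brute(dx, dy) -> float:
    """Pearson correlation over unfolded upper triangles, by explicit loop."""
    n = dx.shape[0]
    xs, ys = [], []
    for i in range(n):
        for j in range(i + 1, n):
            xs.append(dx[i, j])
            ys.append(dy[i, j])
    xs, ys = np.asarray(xs), np.asarray(ys)
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    return float((xs @ ys) / np.sqrt((xs @ xs) * (ys @ ys)))
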