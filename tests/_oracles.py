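"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as explicit double loops over pixels / pairs /
confusion cells, deliberately sharing no code with the package.
"""

import math


def brute_metrics(grid, mask=None):
    """All twelve reflectivity metrics by direct summation over pixels."""
    nrows, ncols = len(grid), len(grid[0])
    if mask is None:
        mask = [[True] * ncols for _ in range(nrows)]
    pixels = []
    for i in range(nrows):
        for j in range(ncols):
            if mask[i][j]:
                pixels.append(float(grid[i][j]))
    n = len(pixels)
    pmax = max(pixels)
    mean = sum(pixels) / n
    energy = sum(p * p for p in pixels) / n
    rel_energy = math.nan if pmax == 0 else sum((p / pmax) ** 2 for p in pixels) / n
    sd_irr = math.nan if pmax == 0 else sum(((p - mean) / pmax) ** 2 for p in pixels) / n
    var = sum((p - mean) ** 2 for p in pixels) / n
    sd = math.sqrt(var)
    srt = sorted(pixels)
    median = srt[(n - 1) // 2]
    counts = {}
    for p in pixels:
        level = int(round(p))
        counts[level] = counts.get(level, 0) + 1
    best_count = max(counts.values())
    mode = min(level for level, c in counts.items() if c == best_count)
    minimum = min(pixels)
    if sd == 0:
        skew = kurt = math.nan
    else:
        m3 = sum((p - mean) ** 3 for p in pixels) / n
        m4 = sum((p - mean) ** 4 for p in pixels) / n
        skew = m3 / var**1.5
        kurt = m4 / var**2
    ent = 0.0
    for c in counts.values():
        q = c / n
        ent -= q * math.log(q)
    ent /= n
    # trapezoid surface integral over the mask bounding box, zero-imputed
    rows = [i for i in range(nrows) if any(mask[i])]
    cols = [j for j in range(ncols) if any(mask[i][j] for i in range(nrows))]
    r0, r1, c0, c1 = min(rows), max(rows), min(cols), max(cols)
    if n < 4 or r1 == r0 or c1 == c0:
        area = math.nan
    else:
        area = 0.0
        for i in range(r0, r1 + 1):
            wr = 0.5 if i in (r0, r1) else 1.0
            for j in range(c0, c1 + 1):
                wc = 0.5 if j in (c0, c1) else 1.0
                v = float(grid[i][j]) if mask[i][j] else 0.0
                area += wr * wc * v
        area /= n
    return {
        "total_area": area,
        "minimum": minimum,
        "energy": energy,
        "relative_energy": rel_energy,
        "entropy": ent,
        "sd_irregularity": sd_irr,
        "mean": mean,
        "sd": sd,
        "median": median,
        "mode": float(mode),
        "kurtosis": kurt,
        "skewness": skew,
    }


def brute_auc(values, labels, positive=1, direction="higher"):
    """Concordant-pair fraction with 0.5 credit for ties."""
    sign = 1.0 if direction == "higher" else -1.0
    pos = [sign * v for v, y in zip(values, labels) if y == positive]
    neg = [sign * v for v, y in zip(values, labels) if y != positive]
    score = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                score += 1.0
            elif p == q:
                score += 0.5
    return score / (len(pos) * len(neg))


def brute_weighted_kappa(a, b, n_grades):
    """Quadratic-weighted kappa from the disagreement form."""
    g = n_grades
    obs = [[0.0] * g for _ in range(g)]
    for x, y in zip(a, b):
        obs[x - 1][y - 1] += 1
    n = len(a)
    row = [sum(obs[i]) for i in range(g)]
    col = [sum(obs[i][j] for i in range(g)) for j in range(g)]
    num = 0.0
    den = 0.0
    for i in range(g):
        for j in range(g):
            w = (i - j) ** 2 / (g - 1) ** 2 if g > 1 else 0.0
            num += w * obs[i][j] / n
            den += w * row[i] * col[j] / n**2
    if den == 0:
        return 1.0
    return 1.0 - num / den
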