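"""Independent brute-force oracle for the shrunken-centroid formulas.

Pure-Python, loop-based, literal transcription of the published estimator:
no numpy vectorization, no code shared with the package implementation.
Used as the ground truth the package must match to 1e-12 on tiny instances.
"""

import math


def oracle_fit(X, y, delta, uniform_priors=True):
    """X: n x g nested lists; y: class label per row.  Returns a dict of
    every intermediate quantity: overall centroid, class centroids, pooled
    SD, s0, m_k, priors, d, d', shrunken centroids."""
    n = len(X)
    g = len(X[0])
    classes = []
    for lab in y:
        if lab not in classes:
            classes.append(lab)
    K = len(classes)
    members = {c: [j for j in range(n) if y[j] == c] for c in classes}
    nk = {c: len(members[c]) for c in classes}

    overall = [sum(X[j][i] for j in range(n)) / n for i in range(g)]
    centroids = {
        c: [sum(X[j][i] for j in members[c]) / nk[c] for i in range(g)]
        for c in classes
    }
    # pooled within-class SD with denominator (n - K)
    s = []
    for i in range(g):
        ss = 0.0
        for c in classes:
            for j in members[c]:
                ss += (X[j][i] - centroids[c][i]) ** 2
        s.append(math.sqrt(ss / (n - K)))
    s0 = _median(s)
    mk = {c: math.sqrt(1.0 / nk[c] - 1.0 / n) for c in classes}
    if uniform_priors:
        priors = {c: 1.0 / K for c in classes}
    else:
        priors = {c: nk[c] / n for c in classes}

    d = {
        c: [
            (centroids[c][i] - overall[i]) / (mk[c] * (s[i] + s0))
            for i in range(g)
        ]
        for c in classes
    }
    dprime = {
        c: [_soft(d[c][i], delta) for i in range(g)] for c in classes
    }
    shrunken = {
        c: [
            overall[i] + mk[c] * (s[i] + s0) * dprime[c][i]
            for i in range(g)
        ]
        for c in classes
    }
    surviving = [
        i for i in range(g) if any(dprime[c][i] != 0.0 for c in classes)
    ]
    return {
        "classes": classes,
        "overall": overall,
        "centroids": centroids,
        "s": s,
        "s0": s0,
        "mk": mk,
        "priors": priors,
        "d": d,
        "dprime": dprime,
        "shrunken": shrunken,
        "surviving": surviving,
    }


def oracle_discriminant(fit, x):
    """delta_k(x) = sum over surviving genes of (x_i - xbar'_ik)^2/(s_i+s0)^2
    - 2 log pi_k."""
    out = {}
    for c in fit["classes"]:
        total = 0.0
        for i in fit["surviving"]:
            denom = fit["s"][i] + fit["s0"]
            total += (x[i] - fit["shrunken"][c][i]) ** 2 / denom**2
        out[c] = total - 2.0 * math.log(fit["priors"][c])
    return out


def oracle_probabilities(fit, x):
    """softmax over -delta_k/2, shifted for numerical stability."""
    disc = oracle_discriminant(fit, x)
    mn = min(disc.values())
    weights = {c: math.exp(-0.5 * (disc[c] - mn)) for c in fit["classes"]}
    z = sum(weights.values())
    return {c: weights[c] / z for c in fit["classes"]}


def oracle_asset_probabilities(centroids, sd, priors, x):
    """Literal two-term discriminant for a frozen panel: centroids used
    directly, sd as the per-gene denominator."""
    disc = {}
    for c in centroids:
        total = 0.0
        for i in range(len(sd)):
            total += (x[i] - centroids[c][i]) ** 2 / sd[i] ** 2
        disc[c] = total - 2.0 * math.log(priors[c])
    mn = min(disc.values())
    weights = {c: math.exp(-0.5 * (disc[c] - mn)) for c in disc}
    z = sum(weights.values())
    return {c: weights[c] / z for c in disc}


def _soft(v, delta):
    mag = abs(v) - delta
    if mag <= 0.0:
        return 0.0
    return math.copysign(mag, v)


def _median(vals):
    s = sorted(vals)
    n = len(s)
    if n % 2:
        return s[n // 2]
    return 0.5 * (s[n // 2 - 1] + s[n // 2])
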