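"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles, without
importing any implementation code from asmram, so that tests compare two
independent routes to the same answer.
"""

from __future__ import annotations

import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def oracle_spectrum(reads, k):
    """Hash-map canonical k-mer counter -> {frequency: n_distinct}."""
    counts = {}
    for read in reads:
        seq = read.upper()
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if any(b not in _COMP for b in window):
                continue
            rc = oracle_revcomp(window)
            kmer = window if window <= rc else rc
            counts[kmer] = counts.get(kmer, 0) + 1
    hist = {}
    for c in counts.values():
        hist[c] = hist.get(c, 0) + 1
    return hist


def oracle_read_stats(reads):
    """One-pass per-read tally: (n, total_bases, gc_fraction, min_len, avg_len)."""
    n = 0
    bases = 0
    gc = 0
    acgt = 0
    min_len = None
    for read in reads:
        seq = read.upper()
        n += 1
        bases += len(seq)
        min_len = len(seq) if min_len is None else min(min_len, len(seq))
        for b in seq:
            if b in ("G", "C"):
                gc += 1
            if b in _COMP:
                acgt += 1
    return n, bases, gc / acgt, min_len, bases / n


def oracle_spectrum_stats(hist):
    """Direct arithmetic over the feature definitions."""
    freqs = sorted(hist)
    v = [f * hist[f] for f in freqs]
    total = sum(v)
    distinct = sum(hist.values())
    mean = total / len(v)
    sd = math.sqrt(sum((x - mean) ** 2 for x in v) / len(v))
    cap = 0.05 * total
    q5 = 0
    for x in v:
        if q5 + x > cap:
            break
        q5 += x
    q95 = 0
    for x in v[::-1]:
        if q95 + x > cap:
            break
        q95 += x
    return {
        "total": total,
        "distinct": distinct,
        "mean": mean,
        "sd": sd,
        "max": max(v),
        "q5": q5,
        "q95": q95,
    }


def oracle_pearson(x, y):
    """Textbook Pearson r plus its two-sided t-transform P-value."""
    from scipy.stats import t as t_dist

    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2.0 * t_dist.sf(abs(t), n - 2)
    return r, p


def oracle_bootstrap_bias(errors, n_boot, statistic, seed, level=0.95):
    """Reimplementation of the documented bootstrap scheme."""
    import numpy as np

    errors = np.asarray(errors, dtype=float)
    rng = np.random.default_rng(seed)
    stats = []
    n = len(errors)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = errors[idx]
        if statistic == "mean":
            stats.append(float(np.mean(sample)))
        else:
            stats.append(float(np.quantile(sample, 0.95)))
    alpha = (1 - level) / 2
    lower = float(np.quantile(stats, alpha))
    upper = float(np.quantile(stats, 1 - alpha))
    return max(0.0, upper), (lower, upper)


def oracle_interpolated_quantile(values, q):
    """Linear-interpolation quantile (type 7), written out longhand."""
    xs = sorted(values)
    pos = q * (len(xs) - 1)
    lo = math.floor(pos)
    hi = math.ceil(pos)
    if lo == hi:
        return float(xs[lo])
    frac = pos - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac


def oracle_fleet(true_peaks, start_ram, catalog_rams):
    """Hand-rolled escalation simulator.

    ``start_ram`` is a mapping dataset -> starting RAM (must be a catalog
    value) or None meaning the smallest sufficient flavor.  Returns
    (per-dataset cost over successful datasets, exhausted ids).
    """
    rams = sorted(catalog_rams)
    costs = {}
    exhausted = []
    for ds, peak in true_peaks.items():
        start = start_ram.get(ds) if start_ram else None
        if start is None:
            fitting = [r for r in rams if r >= peak]
            if not fitting:
                exhausted.append(ds)
                continue
            start = fitting[0]
        idx = rams.index(start)
        cost = 0.0
        done = False
        while idx < len(rams):
            cost += rams[idx]
            if rams[idx] >= peak:
                done = True
                break
            idx += 1
        if done:
            costs[ds] = cost
        else:
            exhausted.append(ds)
    return costs, exhausted


def oracle_top_share(table_dict, samples):
    """Per-sample argmax share; table_dict: species -> {sample: abundance}."""
    species = list(table_dict)
    wins = {s: 0 for s in species}
    for sample in samples:
        column = [(table_dict[s][sample], s) for s in species]
        top = max(v for v, _ in column)
        winners = [s for v, s in column if v == top]
        if len(winners) == 1:
            wins[winners[0]] += 1
    return {s: 100.0 * w / len(samples) for s, w in wins.items()}
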