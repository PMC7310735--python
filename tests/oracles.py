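"""Independent brute-force feature oracles (naive Python loops).

These reimplement every windowed feature directly from its defining
formula, without numpy vectorization and without sharing any code with the
package, so they can serve as an independent cross-check.
"""

import math


def mean(xs):
    return sum(xs) / len(xs)


def sample_std(xs):
    mu = mean(xs)
    return math.sqrt(sum((x - mu) ** 2 for x in xs) / (len(xs) - 1))


def zscore(xs):
    mu = mean(xs)
    sd = sample_std(xs)
    if sd == 0:
        return [0.0 for _ in xs]
    return [(x - mu) / sd for x in xs]


def nmean_reference(xs, rest_mean):
    """Mean deviation from the resting mean (HR/BR normalization)."""
    return mean([x - rest_mean for x in xs])


def nmean_range(xs, rest_min, rest_max):
    """Range-corrected (Lykken) mean for EDA."""
    return mean([(x - rest_min) / (rest_max - rest_min) for x in xs])


def nfd(xs):
    z = zscore(xs)
    return sum(abs(z[i + 1] - z[i]) for i in range(len(z) - 1)) / (len(z) - 1)


def nsd(xs):
    z = zscore(xs)
    return sum(abs(z[i + 2] - z[i]) for i in range(len(z) - 2)) / (len(z) - 2)


def hrv_signed(nni):
    """Mean signed successive difference (telescoping variability statistic)."""
    n = len(nni)
    return sum(nni[i + 1] - nni[i] for i in range(n - 1)) / n


def av_nn(nni):
    return mean(nni)


def sd_nn(nni):
    return sample_std(nni)


def rmssd(nni):
    n = len(nni)
    return math.sqrt(sum((nni[i + 1] - nni[i]) ** 2 for i in range(n - 1)) / (n - 1))


def nn_over(nni, threshold):
    """Successive differences of magnitude at least the threshold."""
    return sum(1 for i in range(len(nni) - 1) if abs(nni[i + 1] - nni[i]) >= threshold)


def pnn(nni, threshold):
    return nn_over(nni, threshold) / (len(nni) - 1)


def mm_or(magnitudes):
    return mean(magnitudes)


def md_or(durations):
    return mean(durations)


def cohens_kappa_reference(matrix):
    """Direct two-loop Cohen's kappa."""
    total = sum(sum(row) for row in matrix)
    k = len(matrix)
    p_o = sum(matrix[i][i] for i in range(k)) / total
    p_e = 0.0
    for i in range(k):
        row = sum(matrix[i])
        col = sum(matrix[j][i] for j in range(k))
        p_e += row * col
    p_e /= total * total
    return (p_o - p_e) / (1 - p_e)
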