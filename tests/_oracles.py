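"""Independent oracles used to freeze expected values in tests.

These deliberately avoid the package's segmentation and estimator code
paths: the run enumerator checks every (start, end) window, and the FST
estimator is the textbook Hudson ratio-of-averages formula.
"""

from __future__ import annotations

import numpy as np


def brute_force_segments(opposing: np.ndarray, positions: np.ndarray,
                         threshold_cM: float, min_snps: int
                         ) -> list[tuple[int, int]]:
    """All maximal zero-opposing windows, by scanning every start/end pair.

    Returns inclusive (start, end) index pairs of retained runs on one
    chromosome.
    """
    n = len(opposing)
    runs = []
    for i in range(n):
        for j in range(i, n):
            if opposing[i:j + 1].any():
                continue
            left_max = i == 0 or opposing[i - 1]
            right_max = j == n - 1 or opposing[j + 1]
            if not (left_max and right_max):
                continue
            span = positions[j] - positions[i]
            if span >= threshold_cM and (j - i + 1) >= min_snps:
                runs.append((i, j))
    return runs


def hudson_fst(counts_a: np.ndarray, n_a: int, counts_b: np.ndarray,
               n_b: int) -> float:
    """Hudson FST estimator (ratio of averages) from allele counts.

    ``counts_*`` are per-SNP counts of the B allele among ``2 * n_*``
    sampled alleles in each population.
    """
    p1 = counts_a / (2 * n_a)
    p2 = counts_b / (2 * n_b)
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / (2 * n_a - 1)
           - p2 * (1 - p2) / (2 * n_b - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.mean() / den.mean())
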