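"""Independent brute-force oracles used by the test suite.

Deliberately naive: Counter-based tabulation, per-cell loops, math.log2, and
a chi-square survival function for the p-value — no code shared with the
package's vectorised implementation.
"""

import itertools
import math
from collections import Counter

from scipy.stats import chi2

MISSING = -1


def oracle_entropy(counts):
    total = sum(counts)
    return -sum((c / total) * math.log2(c / total) for c in counts if c > 0)


def oracle_combo(geno, y, idx):
    """Brute-force (ig, levels_x, n_complete, p_raw) for one SNP combination."""
    cells = Counter()
    for i in range(geno.shape[0]):
        codes = tuple(int(geno[i, j]) for j in idx)
        if MISSING in codes:
            continue
        cells[(codes, int(y[i]))] += 1
    n = sum(cells.values())
    xs = sorted({c for c, _ in cells})
    class_totals = [
        sum(v for (c, lab), v in cells.items() if lab == k) for k in (0, 1)
    ]
    h_y = oracle_entropy(class_totals)
    h_y_x = 0.0
    for x in xs:
        row = [cells.get((x, 0), 0), cells.get((x, 1), 0)]
        h_y_x += (sum(row) / n) * oracle_entropy(row)
    ig = max(h_y - h_y_x, 0.0)
    levels_y = sum(1 for tot in class_totals if tot > 0)
    df = (len(xs) - 1) * (levels_y - 1)
    p = 1.0 if df <= 0 else float(chi2.sf(2 * n * math.log(2) * ig, df))
    return ig, len(xs), n, p


def oracle_scan(geno, y, order):
    """Every combination of the given order, keyed by index tuple."""
    return {
        idx: oracle_combo(geno, y, idx)
        for idx in itertools.combinations(range(geno.shape[1]), order)
    }
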