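"""Independent brute-force evaluations of the population statistics.

Implemented directly from the defining formulas over plain Python lists,
with no shared code with the package: these are the reference the package
implementations are checked against.
"""

from collections import Counter


def oracle_instability(rows) -> float:
    """I = 100 * (sum_t k_t) / T with k_t = 1 - (modal cell count)/N."""
    n = len(rows)
    t_count = len(rows[0])
    total = 0.0
    for t in range(t_count):
        column = [row[t] for row in rows]
        modal = max(Counter(column).values())
        total += 1.0 - modal / n
    return 100.0 * total / t_count


def oracle_anca(rows, euploid) -> float:
    """A = (sum_n q_n) / N, q_n = number of non-euploid chromosomes."""
    q_sum = 0
    for row in rows:
        q_sum += sum(1 for c, e in zip(row, euploid) if c != e)
    return q_sum / len(rows)


def oracle_normalized_anca(rows, euploid) -> float:
    return oracle_anca(rows, euploid) / len(rows[0])


def oracle_aneuploidy(rows, euploid) -> float:
    """D = (1/(T*N)) * sum_n sum_t |c_{n,t} - e_t|."""
    total = sum(abs(c - e) for row in rows for c, e in zip(row, euploid))
    return total / (len(rows) * len(rows[0]))


def oracle_heterogeneity(rows) -> float:
    """H = (1/(T*N)) * sum_t sum_f f * m_{f,t} with per-chromosome state
    counts ordered descending."""
    n = len(rows)
    t_count = len(rows[0])
    total = 0.0
    for t in range(t_count):
        column = [row[t] for row in rows]
        ordered = sorted(Counter(column).values(), reverse=True)
        total += sum(f * m for f, m in enumerate(ordered))
    return total / (t_count * n)


def oracle_classify(row, euploid) -> str:
    if all(c == e for c, e in zip(row, euploid)):
        return "diploid"
    ratios = [c / e for c, e in zip(row, euploid)]
    r = ratios[0]
    if r >= 2 and r == int(r) and all(x == r for x in ratios):
        return "polyploid"
    return "aneuploid"


def oracle_bh(p_values):
    """Step-up BH: sort ascending, q_(i) = min_{j>=i} (m/j) p_(j), cap at 1."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m - 1, -1, -1):
        candidate = min(1.0, m * p_values[order[rank]] / (rank + 1))
        running = min(running, candidate)
        q_sorted[rank] = running
    out = [0.0] * m
    for rank, idx in enumerate(order):
        out[idx] = q_sorted[rank]
    return out


def oracle_collapse_per_basepair(bins, states) -> float:
    """Expand bins of one chromosome to per-basepair states, average, and
    round halves away from zero.  ``bins`` are (start, end); ``states``
    aligned integer states.  Only usable on toy (few-kb) tables."""
    expanded = []
    for (start, end), s in zip(bins, states):
        expanded.extend([s] * (end - start))
    mean = sum(expanded) / len(expanded)
    import math

    return math.floor(mean + 0.5) if mean >= 0 else math.ceil(mean - 0.5)
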