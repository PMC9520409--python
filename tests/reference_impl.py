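"""Straightforward, independent re-implementation of the conduction model,
used as an oracle.  Deliberately simple: python heapq of (time, seq, node)
tuples, per-node dict state, math.exp formulas inline."""

import heapq
import math


def reference_simulate(aa_times, params, chain_length=10, a_r=1.0, a_d=1.0):
    """params: ModelParams-like with .sp/.fp/.cn attributes."""
    L = chain_length
    cn = 2 * L
    n_nodes = 2 * L + 1

    def pathway(node):
        if node < L:
            return params.sp
        if node < 2 * L:
            return params.fp
        return params.cn

    neighbors = {i: [] for i in range(n_nodes)}
    for i in range(L - 1):
        neighbors[i].append(i + 1)
        neighbors[i + 1].append(i)
        neighbors[L + i].append(L + i + 1)
        neighbors[L + i + 1].append(L + i)
    for u, v in [(L - 1, 2 * L - 1), (L - 1, cn), (2 * L - 1, cn)]:
        neighbors[u].append(v)
        neighbors[v].append(u)

    heap = []
    seq = 0
    for t in aa_times:
        heapq.heappush(heap, (float(t), seq, 0))       # SP entry first
        seq += 1
        heapq.heappush(heap, (float(t), seq, L))       # FP entry
        seq += 1

    state = {i: None for i in range(n_nodes)}  # (last_arrival, last_R)
    out = []
    while heap:
        t, _, node = heapq.heappop(heap)
        p = pathway(node)
        if state[node] is None:
            R = a_r * (p.r_min + p.delta_r)
            D = a_d * p.d_min
            conduct = True
        else:
            last_arrival, last_R = state[node]
            gap = t - last_arrival - last_R
            conduct = gap > 0
            if conduct:
                R = a_r * (p.r_min + p.delta_r * (1 - math.exp(-gap / p.tau_r)))
                D = a_d * (p.d_min + p.delta_d * math.exp(-gap / p.tau_d))
        if conduct:
            state[node] = (t, R)
            if node == cn:
                out.append(t + D)
            for nb in sorted(neighbors[node]):
                heapq.heappush(heap, (t + D, seq, nb))
                seq += 1
    return out
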