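"""Independent brute-force oracles used by the test suite."""

import numpy as np


def brute_force_average_linkage_order(data: np.ndarray) -> list[int]:
    """O(n^3) UPGMA agglomeration returning the dendrogram leaf order.

    Average linkage over the original observations; at each step the pair of
    clusters with the smallest mean pairwise Euclidean distance merges, and
    the earlier-formed (smaller-id) cluster's leaves precede the later one's,
    mirroring the standard linkage-matrix traversal convention.
    """
    n = len(data)
    # cluster id -> (member row indices, leaf order)
    clusters: dict[int, tuple[list[int], list[int]]] = {
        i: ([i], [i]) for i in range(n)
    }
    point_dist = np.sqrt(((data[:, None, :] - data[None, :, :]) ** 2).sum(axis=2))
    next_id = n
    while len(clusters) > 1:
        best = None
        ids = sorted(clusters)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                members_a, _ = clusters[a]
                members_b, _ = clusters[b]
                d = float(np.mean(point_dist[np.ix_(members_a, members_b)]))
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        _, a, b = best
        members = clusters[a][0] + clusters[b][0]
        order = clusters[a][1] + clusters[b][1]
        del clusters[a], clusters[b]
        clusters[next_id] = (members, order)
        next_id += 1
    return next(iter(clusters.values()))[1]
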