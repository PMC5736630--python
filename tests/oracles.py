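"""Independent brute-force oracles used only by the test-suite."""
import itertools

import numpy as np


def brute_force_link(a_pos, b_pos, max_displacement):
    """Exhaustively enumerate all one-to-one partial matchings between two
    frames and return (best_cost, best_matching).

    Objective identical to the linker's: sum of squared displacements over
    links (links longer than max_displacement are forbidden) plus
    max_displacement² for every unmatched feature on either side.
    """
    a_pos = np.asarray(a_pos, dtype=float)
    b_pos = np.asarray(b_pos, dtype=float)
    penalty = max_displacement ** 2
    n_a, n_b = len(a_pos), len(b_pos)
    best_cost, best_match = np.inf, None
    for k in range(min(n_a, n_b) + 1):
        for rows in itertools.combinations(range(n_a), k):
            for cols in itertools.permutations(range(n_b), k):
                cost = 0.0
                ok = True
                for r, c in zip(rows, cols):
                    d2 = ((a_pos[r] - b_pos[c]) ** 2).sum()
                    if d2 > penalty:
                        ok = False
                        break
                    cost += d2
                if not ok:
                    continue
                cost += penalty * (n_a - k + n_b - k)
                if cost < best_cost - 1e-12:
                    best_cost = cost
                    best_match = set(zip(rows, cols))
    return best_cost, best_match


def links_from_ensemble(ensemble, frame_a, frame_b, a_pos, b_pos):
    """Extract the (index_in_a, index_in_b) links the linker produced."""
    links = set()
    for t in ensemble.trajectories:
        frames = list(t.frames)
        if frame_a in frames and frame_b in frames:
            pa = t.positions[frames.index(frame_a)] / ensemble.pixel_size
            pb = t.positions[frames.index(frame_b)] / ensemble.pixel_size
            ia = int(np.argmin(((np.asarray(a_pos) - pa) ** 2).sum(axis=1)))
            ib = int(np.argmin(((np.asarray(b_pos) - pb) ** 2).sum(axis=1)))
            links.add((ia, ib))
    return links


def link_cost(links, a_pos, b_pos, max_displacement):
    """Evaluate the linker's objective for a given set of links."""
    a_pos = np.asarray(a_pos, dtype=float)
    b_pos = np.asarray(b_pos, dtype=float)
    penalty = max_displacement ** 2
    cost = sum(((a_pos[r] - b_pos[c]) ** 2).sum() for r, c in links)
    unmatched = (len(a_pos) - len(links)) + (len(b_pos) - len(links))
    return cost + penalty * unmatched
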