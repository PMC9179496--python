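"""Compiled inner loop of the per-step cell update.

All randomness is drawn on demand from the run's single seeded
``numpy.random.Generator`` (shared with the measurement-noise draws), so a
replay from the same seed is bit-exact. The visit order over the sites
occupied at step start is a fresh uniform permutation (Fisher-Yates).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_OFF_Y = np.array([-1, -1, -1, 0, 0, 1, 1, 1], dtype=np.int64)
_OFF_X = np.array([-1, 0, 1, -1, 1, -1, 0, 1], dtype=np.int64)


@njit(cache=True)
def step_cells(
    grid,  # int8 (h, w), 0 = empty; updated in place
    born,  # bool (h, w), scratch, zeroed on entry; daughters are skipped
    conc1,  # float64 (h, w)
    conc2,  # float64 (h, w)
    div_rates,  # float64 (5,) indexed by type code
    bg_death,  # float64
    psi1,  # float64
    psi2,  # float64
    s1,  # float64 (5,) drug-1 sensitivity indicator by type code
    s2,  # float64 (5,)
    repl_prob,  # float64
    mu,  # float64
    mut_targets,  # int8 (5, 3) allowed daughter types, padded with 0
    n_targets,  # int64 (5,)
    rng,  # np.random.Generator
):
    h, w = grid.shape
    born[:, :] = False
    # collect sites occupied at step start
    n = 0
    oy = np.empty(h * w, dtype=np.int64)
    ox = np.empty(h * w, dtype=np.int64)
    for y in range(h):
        for x in range(w):
            if grid[y, x] != 0:
                oy[n] = y
                ox[n] = x
                n += 1
    # uniform random visit order (Fisher-Yates)
    for i in range(n - 1, 0, -1):
        j = int(rng.random() * (i + 1))
        oy[i], oy[j] = oy[j], oy[i]
        ox[i], ox[j] = ox[j], ox[i]
    nb_y = np.empty(8, dtype=np.int64)
    nb_x = np.empty(8, dtype=np.int64)
    em_y = np.empty(8, dtype=np.int64)
    em_x = np.empty(8, dtype=np.int64)
    for k in range(n):
        y = oy[k]
        x = ox[k]
        t = grid[y, x]
        if t == 0 or born[y, x]:
            continue
        p_death = bg_death + s1[t] * conc1[y, x] * psi1 + s2[t] * conc2[y, x] * psi2
        if p_death > 1.0:
            p_death = 1.0
        if rng.random() < p_death:
            grid[y, x] = 0
            continue
        if rng.random() >= div_rates[t]:
            continue
        # enumerate in-bounds Moore neighbors and the empty subset
        n_nb = 0
        n_empty = 0
        for j in range(8):
            yy = y + _OFF_Y[j]
            xx = x + _OFF_X[j]
            if 0 <= yy < h and 0 <= xx < w:
                nb_y[n_nb] = yy
                nb_x[n_nb] = xx
                n_nb += 1
                if grid[yy, xx] == 0:
                    em_y[n_empty] = yy
                    em_x[n_empty] = xx
                    n_empty += 1
        if n_empty > 0:
            j = int(rng.random() * n_empty)
            dy = em_y[j]
            dx = em_x[j]
        elif rng.random() < repl_prob:
            j = int(rng.random() * n_nb)
            dy = nb_y[j]
            dx = nb_x[j]
        else:
            continue
        # daughter inherits the parent type unless it mutates
        daughter = t
        m = rng.random()
        for j in range(n_targets[t]):
            if m < mu * (j + 1):
                daughter = mut_targets[t, j]
                break
        grid[dy, dx] = daughter
        born[dy, dx] = True
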