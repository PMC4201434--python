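import numpy as np
import pytest

import duplipath as dp


def brute_force_peaks(surface, min_prominence=dp.DEFAULT_MIN_PROMINENCE):
    """Exhaustive reference peak finder: plain nested loops over all cells.

    A cell qualifies when its P is >= every existing 8-neighbour; connected
    equal-valued qualifying cells collapse to the lexicographically smallest
    cell.  Kept deliberately independent of the library's filter-based path.
    """
    P = surface.P
    n1, n2 = P.shape
    qualifying = set()
    for i in range(n1):
        for j in range(n2):
            ok = True
            for a in range(max(0, i - 1), min(n1, i + 2)):
                for b in range(max(0, j - 1), min(n2, j + 2)):
                    if (a, b) != (i, j) and P[a, b] > P[i, j]:
                        ok = False
            if ok:
                qualifying.add((i, j))
    # merge connected equal-value plateaus by flood fill
    seen, reps = set(), []
    for cell in sorted(qualifying):
        if cell in seen:
            continue
        stack, comp = [cell], []
        seen.add(cell)
        while stack:
            i, j = stack.pop()
            comp.append((i, j))
            for a in range(i - 1, i + 2):
                for b in range(j - 1, j + 2):
                    if (a, b) in qualifying and (a, b) not in seen:
                        seen.add((a, b))
                        stack.append((a, b))
        reps.append(min(comp))
    floor = surface.floor
    out = []
    for i, j in reps:
        if P[i, j] > floor + min_prominence:
            out.append(
                (float(surface.grid.e1_values[i]), float(surface.grid.e2_values[j]),
                 float(P[i, j]))
            )
    out.sort(key=lambda t: (-t[2], t[0], t[1]))
    return out


def symmetric_copy(o1, o2, rate=0.01, label=""):
    return dp.GeneCopyParams(
        dp.EnvResponse(o1, rate, rate), dp.EnvResponse(o2, rate, rate), label=label
    )


FLAT_COPY = dp.GeneCopyParams(dp.EnvResponse(10), dp.EnvResponse(12), label="flat")


@pytest.fixture(scope="session")
def panel_surfaces():
    """Evaluated default-grid surfaces for every registered panel."""
    return {fid: dp.evaluate_surface(dp.get_figure_config(fid).config)
            for fid in dp.FIGURE_IDS}
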