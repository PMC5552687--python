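"""Independent brute-force oracles shared by the test modules."""

import numpy as np

from mlqmmm.calculators import MuellerBrown


def mueller_brown_saddle_oracle():
    """Grid scan + Newton refinement for the rate-limiting MB saddle.

    Collects every index-1 stationary candidate on a dense grid, Newton-refines
    each, deduplicates, and returns the highest-energy saddle — the one the
    climbing image must converge to on the path between the two deepest
    minima.  Entirely independent of the NEB implementation.
    """
    mb = MuellerBrown()
    xs = np.linspace(-1.2, 0.3, 61)
    ys = np.linspace(0.2, 1.2, 41)
    saddles = []
    for x in xs:
        for y in ys:
            if np.linalg.norm(mb.gradient((x, y))) > 60.0:
                continue
            pt = np.array([x, y])
            try:
                for _ in range(50):
                    pt = pt - np.linalg.solve(mb.hessian(pt), mb.gradient(pt))
            except np.linalg.LinAlgError:
                continue
            if not np.all(np.isfinite(pt)):
                continue
            if np.linalg.norm(mb.gradient(pt)) > 1e-10:
                continue
            ev = np.linalg.eigvalsh(mb.hessian(pt))
            if ev[0] < 0 < ev[1] and not any(
                    np.linalg.norm(pt - s) < 1e-6 for s in saddles):
                saddles.append(pt)
    assert saddles
    return max(saddles, key=mb.energy)
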