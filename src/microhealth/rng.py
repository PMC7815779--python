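"""Counter-based random substreams.

Every stochastic step of the simulation draws its uniforms from a dedicated
substream keyed by ``(master_seed, year, process)``, and the uniform consumed
by an individual is indexed by that individual's integer id.  Consequences:

* permuting the row order of the population never changes any individual's
  draw (order stability);
* two scenarios run with the same master seed share identical uniforms for
  every (individual, year, process) triple — common random numbers (CRN) —
  so scenario contrasts are paired and low-variance;
* skipping a process (e.g. a pinned risk factor in a counterfactual) does not
  shift the randomness of any other process.

Streams are realised with numpy's Philox counter-based bit generator seeded
through :class:`numpy.random.SeedSequence` with the (year, process) pair as
spawn key.
"""

from __future__ import annotations

import numpy as np

# Stable process codes; order matters only in that it must never change.
PROCESS = {
    "mortality": 0,
    "smoker": 1,
    "active": 2,
    "obese": 3,
    "hypertension": 4,
    "depressed": 5,
    # population imputation processes (year key unused, pass year=0)
    "impute_smoker": 101,
    "impute_active": 102,
    "impute_obese": 103,
    "impute_hypertension": 104,
    "impute_depressed": 105,
    "impute_hm": 106,
    "demographics": 110,
}


def stream(master_seed: int, year: int, process: str) -> np.random.Generator:
    """Return the dedicated generator for one (seed, year, process) triple."""
    code = PROCESS[process]
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(year) & 0xFFFFFFFF, code))
    return np.random.Generator(np.random.Philox(ss))


def substream_uniforms(
    master_seed: int, year: int, process: str, ids: np.ndarray
) -> np.ndarray:
    """Uniforms in [0,1) for the given individual ids.

    The full id range ``0..max(id)`` is generated and indexed by ``ids`` so
    that the draw attached to an individual depends only on its id, not on
    which other individuals are present or in what order.
    """
    ids = np.asarray(ids)
    n_total = int(ids.max()) + 1 if ids.size else 0
    u = stream(master_seed, year, process).random(n_total)
    return u[ids]


def substream_normals(
    master_seed: int, year: int, process: str, ids: np.ndarray
) -> np.ndarray:
    """Standard normals indexed by individual id (same keying as uniforms)."""
    ids = np.asarray(ids)
    n_total = int(ids.max()) + 1 if ids.size else 0
    z = stream(master_seed, year, process).standard_normal(n_total)
    return z[ids]
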