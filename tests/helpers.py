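"""Shared construction helpers for the test suite."""

import numpy as np
import pandas as pd


def make_state(n=1, **over):
    """Minimal individual-state frame with overridable columns."""
    base = dict(id=np.arange(n), birth_year=1945, age=66.0, sex="female",
                education="high", country="FR", alive=True, hm=70.0,
                smoker=0, active=0, obese=0, hypertension=0, depressed=0)
    base.update(over)
    return pd.DataFrame(base)
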