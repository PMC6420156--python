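"""Summarise a trajectory with collective-motion order parameters.

Five per-frame scalars: polarisation P, angular momentum M_ang, absolute
angular momentum M_abs (all in [0,1]), mean nearest-neighbour distance
d_a (m), and the percentage of agents moving.
"""

import numpy as np

from swarmtda import ModelParams, compute_all_series, generate_initial_conditions, simulate

ic = generate_initial_conditions(25, "clustered", seed=1)

for kind in ("interactive", "control"):
    traj = simulate(ic, ModelParams(kind=kind), n_frames=500, seed=2)
    series = compute_all_series(traj)
    means = {name: np.nanmean(s.values) for name, s in series.items()}
    print(
        f"{kind:>11}: P={means['P']:.3f}  M_ang={means['M_ang']:.3f}  "
        f"M_abs={means['M_abs']:.3f}  d_a={means['d_a'] * 100:.2f} cm  "
        f"Mov%={means['Mov%']:.1f}"
    )

# d_a and Mov% separate the models sharply (the interactive group stays
# dense and mostly stationary); the model-agnostic P/M_ang/M_abs do not.
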