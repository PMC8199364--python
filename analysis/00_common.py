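"""Shared study conditions for the numbered analysis drivers.

Both bundle topologies are analysed at three noise tiers labelled after the
simulated temperatures of the thermal-stability study (300/350/368 K). The
labels select noise scale factors 1.0 / 2.0 / 3.0 on the per-region
displacement profile (helix 0.012, loop 0.030, tail 0.050 nm).
"""

from pathlib import Path

from helixmd.pipeline import study_config

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1
N_FRAMES = 80
DT = 0.5  # ns per frame


def wtrop_config(n_waters: int = 40) -> dict:
    return study_config("wtrop_like", seed=SEED, n_frames=N_FRAMES, dt=DT,
                        n_waters=n_waters)


def rm6_config() -> dict:
    return study_config("rm6_like", seed=SEED + 100, n_frames=N_FRAMES, dt=DT)
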