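"""Shared study configuration for the numbered analysis scripts.

One demo study at desk scale: 2 dyads x 5 days x 3 conditions, 120-s
sessions, asymptotic interaction strength 0.5 (the regime where the
measured interbrain correlation plateaus near 0.4), human leading by 1 s,
with the attention effect (frontal theta reduced during interaction)
switched on.  All scripts regenerate sessions deterministically from
SEED, so every table in results/ can be reproduced bit-for-bit.
"""

from pathlib import Path

from dyadscan.synthetic import StudyDesign, build_study

SEED = 20240901
RESULTS = Path(__file__).resolve().parent.parent / "results"

DESIGN = StudyDesign(
    n_dyads=2,
    days=5,
    duration=120.0,
    strength=0.5,
    lag=500,
    attention_theta_gain=0.7,
    channels_per_region=2,
)


def demo_study():
    RESULTS.mkdir(exist_ok=True)
    return build_study(DESIGN, seed=SEED)
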