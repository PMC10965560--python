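"""Frozen synthetic study conditions for validation and demonstration.

Two scenarios are fixed here so that tests, the reproduction script and the
documentation all exercise the same conditions:

* **recovery** — eight strong gamma-band couplings planted on the eight
  reference channels of the portable montage, one VAD component each; used
  to check that the EII ranking recovers the planted channels.
* **strong** — near-maximal couplings of three channels per VAD component
  with low noise; used for end-to-end classification and streaming checks,
  where the discretized ratings are recoverable from band power.

Sizes are desk-scale (a few subjects, short trials) so the full pipeline
runs in minutes on one CPU; the generator's *defaults* remain the full
benchmark shape.
"""

from __future__ import annotations

from .montage import OPTIMAL_CHANNELS_8
from .recordings import EffectSpec, GeneratorConfig
from .spectral import WindowSpec

#: VAD component planted on each reference channel in the recovery scenario.
RECOVERY_COMPONENTS = {
    "Fp1": "arousal",
    "F7": "valence",
    "FC5": "dominance",
    "FC6": "arousal",
    "T7": "valence",
    "T8": "dominance",
    "P7": "arousal",
    "O2": "valence",
}


def recovery_effect() -> EffectSpec:
    """Eight gamma-band couplings on the reference channels, moderate noise."""
    return EffectSpec(
        couplings=tuple(
            (ch, "gamma", comp, 2.0) for ch, comp in RECOVERY_COMPONENTS.items()
        ),
        noise_sd=0.3,
        baseline_amplitude=10.0,
    )


def recovery_config() -> GeneratorConfig:
    return GeneratorConfig(n_subjects=8, trials_per_subject=4, trial_duration_s=12.0)


def recovery_windows() -> WindowSpec:
    return WindowSpec(length_s=2.0, step_s=0.5)


#: Channels coupled to each VAD component in the strong scenario.
STRONG_COMPONENTS = {
    "valence": ("F7", "T7", "P7"),
    "arousal": ("Fp1", "FC6", "O2"),
    "dominance": ("FC5", "T8", "P7"),
}


def strong_effect() -> EffectSpec:
    """Near-maximal slope (amplitude stays positive over the 1-9 range),
    low noise: classes are recoverable from gamma band power."""
    couplings = tuple(
        (ch, "gamma", comp, 2.4)
        for comp, chans in STRONG_COMPONENTS.items()
        for ch in chans
    )
    return EffectSpec(couplings=couplings, noise_sd=0.1, baseline_amplitude=10.0)


def strong_config() -> GeneratorConfig:
    return GeneratorConfig(n_subjects=2, trials_per_subject=30, trial_duration_s=10.0)


def strong_windows() -> WindowSpec:
    return WindowSpec(length_s=2.0, step_s=0.25)


#: Forest size used for desk-scale selection runs (full runs use 100).
SELECTION_TREES = 25
SELECTION_ITERATIONS = 10
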