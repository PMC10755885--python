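"""Seeded generator of five-class surrogate EEG with Bonn-matching dimensions.

The generator is phenomenological: each class is a recipe of colored
background noise, narrow-band oscillations, Poisson-timed interictal spikes
and (for the ictal class) large slow bursts.  It does not model cortical
physics; its job is to carry class-discriminative structure in the same
shape as the Bonn corpus — five subsets, 100 segments of 4097 samples at
173.61 Hz — including the one amplitude fact that matters clinically: ictal
(E) voltages exceed 1000 uV while the other classes stay on a ~100 uV scale.

Default recipes:

* A — healthy, eyes open: broadband noise with weak alpha (8-13 Hz).
* B — healthy, eyes closed: same background, much stronger alpha.
* C — interictal, opposite hemisphere: theta rhythm plus sparse spikes.
* D — interictal, epileptogenic zone: stronger theta, frequent spikes.
* E — ictal: high-amplitude rhythmic 3-7 Hz discharge in bursts.

A ``separability`` knob in [0, 1] linearly interpolates every recipe toward
the A recipe: at 0 all five classes are statistically identical (a chance
control), at 1 the full class structure is present.

Samples are rounded to whole microvolts, mirroring the integer ADC output of
the real recordings and making ASCII export/re-import lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .windowing import DEFAULT_FS, SUBSET_LABELS, EEGSegment, WindowedDataset, build_windowed_dataset

__all__ = [
    "ClassRecipe",
    "SyntheticCorpus",
    "default_recipes",
    "generate_segment",
    "generate_subset",
    "generate_corpus",
]


@dataclass(frozen=True)
class ClassRecipe:
    """Spectral/event parameters for one class, amplitudes in microvolts."""

    label: str
    noise_std: float = 30.0  # broadband background
    osc_freq: tuple[float, float] = (8.0, 13.0)  # oscillation band (Hz)
    osc_amplitude: float = 20.0
    spike_rate: float = 0.0  # interictal spikes per second
    spike_amplitude: float = 0.0
    burst_freq: tuple[float, float] = (3.0, 7.0)  # ictal burst band (Hz)
    burst_amplitude: float = 0.0  # peak amplitude of ictal discharge


def default_recipes() -> dict[str, ClassRecipe]:
    return {
        "A": ClassRecipe("A", noise_std=30.0, osc_freq=(8.0, 13.0), osc_amplitude=20.0),
        "B": ClassRecipe("B", noise_std=30.0, osc_freq=(8.0, 13.0), osc_amplitude=110.0),
        "C": ClassRecipe(
            "C",
            noise_std=35.0,
            osc_freq=(4.0, 7.0),
            osc_amplitude=55.0,
            spike_rate=1.0,
            spike_amplitude=250.0,
        ),
        "D": ClassRecipe(
            "D",
            noise_std=40.0,
            osc_freq=(4.0, 7.0),
            osc_amplitude=80.0,
            spike_rate=4.0,
            spike_amplitude=350.0,
        ),
        "E": ClassRecipe(
            "E",
            noise_std=60.0,
            osc_freq=(3.0, 7.0),
            osc_amplitude=0.0,
            burst_freq=(3.0, 7.0),
            burst_amplitude=1300.0,
        ),
    }


def _blend(recipe: ClassRecipe, base: ClassRecipe, s: float) -> ClassRecipe:
    """Interpolate ``recipe`` toward ``base``: s=1 keeps it, s=0 gives base."""
    lerp = lambda a, b: b + s * (a - b)
    return replace(
        recipe,
        noise_std=lerp(recipe.noise_std, base.noise_std),
        osc_freq=(
            lerp(recipe.osc_freq[0], base.osc_freq[0]),
            lerp(recipe.osc_freq[1], base.osc_freq[1]),
        ),
        osc_amplitude=lerp(recipe.osc_amplitude, base.osc_amplitude),
        spike_rate=lerp(recipe.spike_rate, base.spike_rate),
        spike_amplitude=lerp(recipe.spike_amplitude, base.spike_amplitude),
        burst_amplitude=lerp(recipe.burst_amplitude, base.burst_amplitude),
    )


def _colored_noise(rng: np.random.Generator, n: int, std: float) -> np.ndarray:
    # AR(1) low-passed white noise, variance-normalised: crude 1/f-ish background.
    from scipy.signal import lfilter

    white = rng.standard_normal(n)
    rho = 0.8
    out = lfilter([1.0], [1.0, -rho], white)
    out *= std * np.sqrt(1.0 - rho**2)
    return out


def _spike_train(
    rng: np.random.Generator, n: int, fs: float, rate: float, amplitude: float
) -> np.ndarray:
    """Poisson-timed sharp biphasic transients (interictal spikes)."""
    out = np.zeros(n)
    if rate <= 0 or amplitude <= 0:
        return out
    n_events = rng.poisson(rate * n / fs)
    width = max(int(0.07 * fs), 3)  # ~70 ms sharp wave
    t = np.arange(width) / width
    shape = np.sin(np.pi * t) * np.exp(-4.0 * t)  # fast up, slower decay
    for _ in range(n_events):
        start = int(rng.integers(0, max(n - width, 1)))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        amp = amplitude * rng.uniform(0.7, 1.3)
        out[start : start + width] += sign * amp * shape[: n - start]
    return out


def generate_segment(
    recipe: ClassRecipe,
    rng: np.random.Generator,
    n_samples: int = 4097,
    fs: float = DEFAULT_FS,
) -> EEGSegment:
    """Synthesize one segment from a recipe using the supplied generator."""
    t = np.arange(n_samples) / fs
    x = _colored_noise(rng, n_samples, recipe.noise_std)
    if recipe.osc_amplitude > 0:
        freq = rng.uniform(*recipe.osc_freq)
        phase = rng.uniform(0, 2 * np.pi)
        # slow amplitude modulation so the rhythm waxes and wanes
        mod = 1.0 + 0.3 * np.sin(2 * np.pi * rng.uniform(0.05, 0.2) * t + rng.uniform(0, 2 * np.pi))
        x += recipe.osc_amplitude * mod * np.sin(2 * np.pi * freq * t + phase)
    x += _spike_train(rng, n_samples, fs, recipe.spike_rate, recipe.spike_amplitude)
    if recipe.burst_amplitude > 0:
        freq = rng.uniform(*recipe.burst_freq)
        phase = rng.uniform(0, 2 * np.pi)
        # rhythmic discharge with burst-suppression envelope, never fully off
        env = 0.55 + 0.45 * np.sin(2 * np.pi * rng.uniform(0.1, 0.3) * t + rng.uniform(0, 2 * np.pi))
        x += recipe.burst_amplitude * env * np.sin(2 * np.pi * freq * t + phase)
    x = np.rint(x)  # integer microvolts, as digitised EEG
    return EEGSegment(samples=x, sampling_rate=fs, subset_label=recipe.label if recipe.label in SUBSET_LABELS else None)


def generate_subset(
    label: str,
    n_segments: int = 100,
    n_samples: int = 4097,
    fs: float = DEFAULT_FS,
    seed: int = 0,
    separability: float = 1.0,
    recipes: Mapping[str, ClassRecipe] | None = None,
    rng: np.random.Generator | None = None,
) -> list[EEGSegment]:
    """Generate one subset (a list of seeded segments) for class ``label``."""
    recipes = dict(recipes) if recipes is not None else default_recipes()
    if label not in recipes:
        raise ValueError(f"unknown subset label {label!r}; expected one of {sorted(recipes)}")
    if rng is None:
        rng = np.random.default_rng(seed)
    recipe = _blend(recipes[label], recipes["A"], separability)
    return [generate_segment(recipe, rng, n_samples, fs) for _ in range(n_segments)]


@dataclass
class SyntheticCorpus:
    """A full five-subset surrogate corpus plus its generation provenance."""

    subsets: dict[str, list[EEGSegment]]
    seed: int
    separability: float
    recipes: dict[str, ClassRecipe] = field(default_factory=default_recipes)

    @property
    def shape(self) -> tuple[int, int, int]:
        n_seg = len(next(iter(self.subsets.values())))
        n_samp = len(next(iter(self.subsets.values()))[0])
        return (len(self.subsets), n_seg, n_samp)

    def to_windowed(self, chunk_len: int = 178) -> WindowedDataset:
        return build_windowed_dataset(self.subsets, chunk_len=chunk_len)

    def export(self, root) -> list:
        from .bonn import export_corpus

        return export_corpus(self, root)


def generate_corpus(
    n_segments: int = 100,
    n_samples: int = 4097,
    fs: float = DEFAULT_FS,
    seed: int = 0,
    separability: float = 1.0,
    recipes: Mapping[str, ClassRecipe] | None = None,
) -> SyntheticCorpus:
    """Generate all five subsets from one seeded generator.

    A single ``numpy`` Generator drives every draw, so regeneration with the
    same arguments is bit-identical regardless of platform.
    """
    recipes = dict(recipes) if recipes is not None else default_recipes()
    rng = np.random.default_rng(seed)
    subsets = {
        label: generate_subset(
            label,
            n_segments=n_segments,
            n_samples=n_samples,
            fs=fs,
            separability=separability,
            recipes=recipes,
            rng=rng,
        )
        for label in sorted(recipes)
    }
    return SyntheticCorpus(subsets=subsets, seed=seed, separability=separability, recipes=dict(recipes))
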