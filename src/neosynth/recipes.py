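"""The five training-set recipes and the generative chain.

Synthesis-based recipes build every training image from a label map:
random per-tissue contrast, spatial deformation (affine + elastic), bias
field and noise, optionally k-space motion corruption, and final min-max
normalization. Two enrichments address neonatal-specific appearance:

* ``SynthMot`` adds the motion simulation with probability .5;
* ``SynthInh`` swaps in a WM-subdivided label map with probability .5, so
  the immature WM gets several independent random intensities;
* ``SynthMotInh`` combines both (each gated at .5);
* ``DataT2`` is the real-image baseline: the subject's (T2-like) intensity
  volume with the same augmentation minus random contrast and motion, plus
  a random gamma perturbation.

Every generated sample carries a provenance record: the per-sample seed,
every transform's parameters and whether each probability gate fired; a
sample is exactly regenerable from its provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml

from . import artifacts, spatial, synthesis
from .core import Image, LabelMap, SurfacePair
from .phantom import PhantomSpec, calibrate_gt_bias, make_phantom, \
    make_gt_variants
from .wm_subdivision import SubdivisionResult, regroup, subdivide_wm

RECIPE_NAMES = ("Synth", "SynthMot", "SynthInh", "SynthMotInh", "DataT2")

#: Fixed contrast tables emulating the two standard anatomical sequences in
#: the neonatal period (T2w: CSF bright, WM brighter than cortical GM;
#: T1w: roughly inverted, WM darker than GM before myelination).
T2_LIKE_CONTRAST = {
    0: (0.03, 0.02), 1: (0.30, 0.05), 2: (0.90, 0.04), 3: (0.55, 0.04),
    4: (0.74, 0.04), 5: (0.92, 0.04), 6: (0.48, 0.04), 7: (0.58, 0.04),
    8: (0.46, 0.04), 9: (0.60, 0.04),
}
T1_LIKE_CONTRAST = {
    0: (0.03, 0.02), 1: (0.62, 0.05), 2: (0.14, 0.04), 3: (0.46, 0.04),
    4: (0.28, 0.04), 5: (0.12, 0.04), 6: (0.56, 0.04), 7: (0.44, 0.04),
    8: (0.58, 0.04), 9: (0.42, 0.04),
}


@dataclass
class RecipeConfig:
    """One training-set recipe: which transforms run and their gates."""

    name: str
    random_contrast: bool = True
    motion_prob: float = 0.0
    wm_inh_prob: float = 0.0
    gamma: bool = False
    use_real_image: bool = False
    wm_clusters: tuple[int, ...] = (2, 3, 4, 5, 6)

    def __post_init__(self):
        if not 0.0 <= self.motion_prob <= 1.0:
            raise ValueError("motion_prob must lie in [0, 1]")
        if not 0.0 <= self.wm_inh_prob <= 1.0:
            raise ValueError("wm_inh_prob must lie in [0, 1]")
        if self.use_real_image and self.random_contrast:
            raise ValueError("a real-image recipe cannot use random "
                             "contrast")


def recipe_config(name: str) -> RecipeConfig:
    configs = {
        "Synth": RecipeConfig("Synth"),
        "SynthMot": RecipeConfig("SynthMot", motion_prob=0.5),
        "SynthInh": RecipeConfig("SynthInh", wm_inh_prob=0.5),
        "SynthMotInh": RecipeConfig("SynthMotInh", motion_prob=0.5,
                                    wm_inh_prob=0.5),
        "DataT2": RecipeConfig("DataT2", random_contrast=False,
                               gamma=True, use_real_image=True),
    }
    if name not in configs:
        raise ValueError(f"unknown recipe {name!r}; choose from "
                         f"{RECIPE_NAMES}")
    return configs[name]


@dataclass
class Subject:
    """A labelled training/testing subject.

    ``image`` is the subject's reference intensity volume (required by
    DataT2 and by the WM subdivision); ``label_map`` the ground-truth label
    map used both as generative substrate and as target.
    """

    subject_id: str
    label_map: LabelMap
    surfaces: SurfacePair | None = None
    image: Image | None = None
    age_weeks: float | None = None
    _wm_subdivisions: dict[int, SubdivisionResult] = field(
        default_factory=dict, repr=False)

    def wm_subdivision(self, n_clusters: int) -> SubdivisionResult:
        """The WM subdivision is a fixed modification of the input labels:
        computed once per subject and cluster count, then cached."""
        if self.image is None:
            raise ValueError(
                f"subject {self.subject_id!r} has no intensity volume; "
                "WM subdivision requires one")
        if n_clusters not in self._wm_subdivisions:
            self._wm_subdivisions[n_clusters] = subdivide_wm(
                self.label_map, self.image, n_clusters)
        return self._wm_subdivisions[n_clusters]


def draw_gates(recipe: RecipeConfig, rng: np.random.Generator) -> dict:
    """Draw the per-sample probability gates (always both draws, so the
    random stream is aligned across recipes)."""
    u_motion = rng.random()
    u_wm = rng.random()
    return {
        "motion": bool(u_motion < recipe.motion_prob),
        "wm_inh": bool(u_wm < recipe.wm_inh_prob),
    }


def generate_training_sample(recipe: RecipeConfig, subject: Subject,
                             rng: np.random.Generator
                             ) -> tuple[Image, LabelMap, dict]:
    """Generate one (image, target label map, provenance) training sample.

    Chain order: WM-subdivision swap (gated), spatial deformation of the
    label set (nearest-neighbour; the image too for a real-image recipe),
    random contrast rendering (synthesis recipes) or the real image, bias
    field, noise, motion (gated), gamma (real-image recipe), min-max
    normalization. The target is the deformed label map regrouped to the
    ten target classes.
    """
    if recipe.use_real_image and subject.image is None:
        raise ValueError(f"recipe {recipe.name!r} needs a real intensity "
                         f"volume but subject {subject.subject_id!r} has "
                         "none")
    sample_seed = int(rng.integers(2 ** 31))
    return regenerate_training_sample(recipe, subject, sample_seed)


def regenerate_training_sample(recipe: RecipeConfig, subject: Subject,
                               sample_seed: int
                               ) -> tuple[Image, LabelMap, dict]:
    """Deterministic sample generation from a per-sample seed (the function
    behind :func:`generate_training_sample`; provenance records the seed)."""
    rng = np.random.default_rng(sample_seed)
    prov: dict = {"recipe": recipe.name, "sample_seed": sample_seed,
                  "subject_id": subject.subject_id, "transforms": []}

    gates = draw_gates(recipe, rng)
    prov["gates"] = gates

    gen_labels = subject.label_map
    grouping = {int(l): int(l) for l in gen_labels.palette}
    if gates["wm_inh"] and recipe.wm_inh_prob > 0:
        n_clusters = int(recipe.wm_clusters[
            rng.integers(len(recipe.wm_clusters))])
        sub = subject.wm_subdivision(n_clusters)
        gen_labels = sub.relabeled
        grouping = sub.grouping
        prov["transforms"].append({"name": "wm_subdivision",
                                   "n_clusters": n_clusters})

    aff = spatial.sample_affine(rng)
    ela = spatial.sample_elastic(rng)
    gen_labels = spatial.apply_affine(gen_labels, aff, "nearest")
    gen_labels = spatial.apply_elastic(gen_labels, ela, "nearest")
    prov["transforms"].append({"name": "affine", **aff.to_config()})
    prov["transforms"].append({
        "name": "elastic", "control_points": ela.control_points,
        "max_displacement_mm": ela.max_displacement_mm})

    if recipe.random_contrast:
        contrast = synthesis.sample_contrast(gen_labels.present_labels(),
                                             rng)
        image = synthesis.render_image(gen_labels, contrast, rng)
        prov["transforms"].append({"name": "random_contrast",
                                   "contrast": contrast.to_config()})
    else:
        image = spatial.apply_affine(subject.image, aff, "linear")
        image = spatial.apply_elastic(image, ela, "linear")
        prov["transforms"].append({"name": "real_image"})

    bias = artifacts.sample_bias_field(rng)
    image = artifacts.apply_bias(image, bias)
    prov["transforms"].append({"name": "bias_field",
                               "coefficients": bias.coefficients.tolist()})

    noise = artifacts.sample_noise(rng)
    image = artifacts.apply_noise(image, noise, rng)
    prov["transforms"].append({"name": "noise", "std": noise.std})

    if gates["motion"] and recipe.motion_prob > 0:
        mpar = artifacts.sample_motion_params(rng)
        n_segments = image.shape[1]
        traj = artifacts.sample_trajectory(mpar, n_segments, rng)
        background = gen_labels.mask("background")
        image = artifacts.apply_motion(image, traj,
                                       background_mask=background)
        prov["transforms"].append({
            "name": "motion",
            "max_translation_mm": mpar.max_translation_mm,
            "max_rotation_deg": mpar.max_rotation_deg,
            "event_segment": traj.event_segment,
            "ramp_segments": traj.ramp_segments})

    if recipe.gamma:
        image = synthesis.normalize_intensity(image)
        log_gamma = artifacts.sample_log_gamma(rng)
        image = artifacts.apply_gamma(image, log_gamma)
        prov["transforms"].append({"name": "gamma",
                                   "log_gamma": log_gamma})

    image = synthesis.normalize_intensity(image)
    prov["transforms"].append({"name": "normalize"})

    target = regroup(gen_labels, grouping)
    return image, target, prov


def write_provenance(prov: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(prov, sort_keys=False))


def read_provenance(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


# --------------------------------------------------------------------------
# Phantom cohorts
# --------------------------------------------------------------------------

def render_canonical(label_map: LabelMap, contrast_table: dict,
                     seed: int) -> Image:
    """A fixed-contrast 'acquired' rendering of a phantom: piecewise
    Gaussian intensities from a standard contrast table, mild bias and
    noise, normalized to [0, 1]. Serves as the real image of the phantom
    world (DataT2 training, test-time prediction input)."""
    rng = np.random.default_rng(seed)
    contrast = synthesis.ContrastSample.from_table(contrast_table)
    img = synthesis.render_image(label_map, contrast, rng)
    bias = artifacts.BiasFieldParams(
        artifacts.sample_bias_field(rng, max_magnitude=0.1).coefficients)
    img = artifacts.apply_bias(img, bias)
    img = artifacts.apply_noise(img, artifacts.NoiseParams(std=0.01), rng)
    return synthesis.normalize_intensity(img)


def make_cohort(n_subjects: int, seed: int,
                grid_shape=(48, 48, 48), voxel_size=1.0,
                folding_range=(0.1, 0.9), cortical_thickness: float = 3.0,
                ground_truth: str = "native",
                contrast_table: dict | None = None,
                gt_ratio_target: float | None = None) -> list[Subject]:
    """Seeded phantom cohort with folding (pseudo-age) uniformly spread
    over ``folding_range``.

    ``ground_truth`` selects the subjects' label maps: ``"native"`` (the
    phantom's own labels), ``"tight"`` (surface GM at threshold 0.5) or
    ``"large"`` (surface GM with the bias calibrated per phantom to the GM
    volume ratio target). Each subject carries a canonical T2-like
    rendering as its intensity volume.
    """
    if ground_truth not in ("native", "tight", "large"):
        raise ValueError("ground_truth must be native, tight or large")
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_subjects)
    foldings = np.linspace(*folding_range, n_subjects)
    table = contrast_table if contrast_table is not None \
        else T2_LIKE_CONTRAST
    subjects = []
    for i in range(n_subjects):
        spec = PhantomSpec(grid_shape, voxel_size, float(foldings[i]),
                           cortical_thickness,
                           seed=int(seeds[2 * i] % (2 ** 31)))
        native, surfaces = make_phantom(spec)
        # the canonical image always reflects the native anatomy: a ground
        # truth variant is an annotation bias, not a change in the image
        image = render_canonical(native, table,
                                 seed=int(seeds[2 * i + 1] % (2 ** 31)))
        label_map = native
        if ground_truth == "tight":
            label_map, _ = make_gt_variants(native, surfaces, 0.0)
        elif ground_truth == "large":
            from .phantom import GM_VOLUME_RATIO_TARGET
            ratio = gt_ratio_target if gt_ratio_target is not None \
                else GM_VOLUME_RATIO_TARGET
            bias = calibrate_gt_bias(native, surfaces, target_ratio=ratio)
            _, label_map = make_gt_variants(native, surfaces, bias)
        subjects.append(Subject(
            subject_id=f"phantom-{seed}-{i:03d}",
            label_map=label_map, surfaces=surfaces, image=image,
            age_weeks=spec.pseudo_age_weeks))
    return subjects


def sample_stream(recipe: RecipeConfig, subjects: Sequence[Subject]
                  ) -> Callable:
    """A ``(rng) -> (Image, LabelMap)`` closure cycling over subjects, for
    :func:`neosynth.training.train`."""
    state = {"i": 0}

    def generator(rng: np.random.Generator):
        subject = subjects[state["i"] % len(subjects)]
        state["i"] += 1
        image, target, _ = generate_training_sample(recipe, subject, rng)
        return image, target

    return generator
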