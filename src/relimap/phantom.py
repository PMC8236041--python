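"""Synthetic multi-subject, multi-session, multi-condition map phantoms.

The generator draws spatial maps from the two-level Gaussian variance-
component model that underlies test-retest reliability analysis:

    Y[i, s, v] = mu[v] + b[i, v] + eps[i, s, v]

with a fixed mean pattern mu, a subject effect b ~ N(0, sigma2_between[v])
drawn once per subject, and session noise eps ~ N(0, sigma2_within[v])
drawn independently per session. The true consistency ICC per voxel is
then sigma2_between / (sigma2_between + sigma2_within), so every analysis
stage (ICC maps, overlap, fingerprinting) can be validated by parameter
recovery against known truth.

Multi-condition stacks add a sharing structure between condition mean
patterns: mu_c = scale * (sqrt(lambda) * C + sqrt(1 - lambda) * U_c) with
C and U_c independent unit-variance fields, so the expected spatial
correlation between two condition maps of one subject is analytic (see
:class:`PhantomTruth`). Difference conditions (e.g. food minus neutral)
are formed by literal subtraction of the generated maps, reproducing the
reliability attenuation that subtraction causes when conditions share
variance.

Randomness uses one master seed with per-(subject, session, condition)
sub-streams (``numpy`` SeedSequence keyed on indices), so the same spec
and seed are bit-reproducible and adding a subject does not perturb the
data of existing subjects.

Realistic anatomy is out of scope: optional box/sphere "active regions"
with elevated amplitude and their own variance components stand in for
activation topography, and an optional separable Gaussian smoothing
kernel (mean-preserving) induces spatial dependence when wanted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import BrainMask, MapStack, RatingsTable, VolumeGrid, write_map

GENERATOR_VERSION = "1"

# sub-stream tags keep subject/session/condition draws on disjoint streams
_TAG_FIELD = 11
_TAG_SUBJECT = 23
_TAG_SESSION = 37


@dataclass(frozen=True)
class Region:
    """A box- or sphere-shaped voxel set with its own variance components."""

    name: str
    sigma2_between: float
    sigma2_within: float
    amplitude: float = 0.0
    box: tuple[tuple[int, int, int], tuple[int, int, int]] | None = None  # lo, hi (excl.)
    sphere: tuple[tuple[float, float, float], float] | None = None  # center, radius

    def voxel_mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        if (self.box is None) == (self.sphere is None):
            raise ValueError(f"region {self.name!r}: give exactly one of box or sphere")
        if self.box is not None:
            lo, hi = self.box
            m = np.zeros(shape, dtype=bool)
            m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
            return m
        center, radius = self.sphere
        grids = np.indices(shape, dtype=float)
        d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        return d2 <= radius**2


@dataclass
class PhantomSpec:
    """Generating parameters of a synthetic map stack."""

    shape: tuple[int, int, int] = (12, 12, 12)
    n_subjects: int = 11
    sessions: tuple[str, ...] = ("T0", "T1", "T2")
    conditions: tuple[str, ...] = ("food_minus_neutral",)
    sigma2_between: float = 1.0   # background between-subject variance
    sigma2_within: float = 1.0    # background within-subject (session) variance
    amplitude: float = 0.0        # background mean
    regions: tuple[Region, ...] = ()
    smoothing_sigma: float = 0.0  # isotropic Gaussian sigma, voxels
    pseudo_t_se: float | None = None  # divide maps by this nominal SE
    pseudo_t_df: int | None = None    # df to quote for the pseudo-t maps
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.sigma2_within <= 0 or any(r.sigma2_within <= 0 for r in self.regions):
            raise ValueError("sigma2_within must be > 0 everywhere (ICC degenerate)")
        if self.sigma2_between < 0 or any(r.sigma2_between < 0 for r in self.regions):
            raise ValueError("sigma2_between must be >= 0")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")
        taken = np.zeros(self.shape, dtype=bool)
        for r in self.regions:
            m = r.voxel_mask(self.shape)
            if (taken & m).any():
                raise ValueError(f"region {r.name!r} overlaps an earlier region")
            taken |= m

    def parameter_maps(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(mu, sigma2_between, sigma2_within) full-grid volumes."""
        mu = np.full(self.shape, float(self.amplitude))
        s2b = np.full(self.shape, float(self.sigma2_between))
        s2w = np.full(self.shape, float(self.sigma2_within))
        for r in self.regions:
            m = r.voxel_mask(self.shape)
            mu[m] = r.amplitude
            s2b[m] = r.sigma2_between
            s2w[m] = r.sigma2_within
        return mu, s2b, s2w

    def full_mask(self) -> BrainMask:
        grid = VolumeGrid(self.shape, np.eye(4))
        return BrainMask(grid, np.arange(int(np.prod(self.shape))))


@dataclass
class PhantomTruth:
    """Ground truth of a generated stack: what recovery tests check against."""

    true_icc: np.ndarray                   # per in-mask voxel
    sigma2_between: np.ndarray
    sigma2_within: np.ndarray
    sharing: float | None = None           # lambda of the condition model
    pattern_scale: float | None = None
    expected_rho_pearson: float | None = None   # cross-condition, same session
    expected_rho_spearman: float | None = None
    expected_retest_r: float | None = None      # per-condition test-retest r
    expected_difference_retest_r: float | None = None
    true_difference_icc: float | None = None    # voxel-wise ICC of difference maps
    seed: int = 0
    generator_version: str = GENERATOR_VERSION

    def summary(self) -> dict:
        out = {
            "mean_true_icc": float(np.mean(self.true_icc)),
            "sharing": self.sharing,
            "pattern_scale": self.pattern_scale,
            "expected_rho_pearson": self.expected_rho_pearson,
            "expected_rho_spearman": self.expected_rho_spearman,
            "expected_retest_r": self.expected_retest_r,
            "expected_difference_retest_r": self.expected_difference_retest_r,
            "true_difference_icc": self.true_difference_icc,
            "seed": self.seed,
            "generator_version": self.generator_version,
        }
        return {k: v for k, v in out.items() if v is not None}


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *map(int, key)])


def _smooth(vol: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return vol
    # nearest-edge handling keeps the kernel mean-preserving on constants
    return ndimage.gaussian_filter(vol, sigma=sigma, mode="nearest")


def generate_stack(spec: PhantomSpec) -> tuple[MapStack, PhantomTruth]:
    """Draw a complete MapStack from the two-level variance-component model.

    Conditions in ``spec.conditions`` share the deterministic mean pattern
    but receive independent subject and session effects (use
    :func:`generate_condition_stack` for correlated condition structure).
    """
    mu, s2b, s2w = spec.parameter_maps()
    mask = spec.full_mask()
    sd_b, sd_w = np.sqrt(s2b), np.sqrt(s2w)
    n, sessions, conditions = spec.n_subjects, list(spec.sessions), list(spec.conditions)
    values = np.empty((n, len(sessions), len(conditions), mask.n_voxels))
    for c in range(len(conditions)):
        for i in range(n):
            b = _rng(spec.seed, _TAG_SUBJECT, i, c).standard_normal(spec.shape) * sd_b
            for s in range(len(sessions)):
                eps = (
                    _rng(spec.seed, _TAG_SESSION, i, s, c).standard_normal(spec.shape)
                    * sd_w
                )
                vol = _smooth(mu + b + eps, spec.smoothing_sigma)
                if spec.pseudo_t_se is not None:
                    vol = vol / spec.pseudo_t_se
                values[i, s, c] = vol.ravel()[mask.indices]
    subjects = [f"sub-{i + 1:03d}" for i in range(n)]
    present = np.ones((n, len(sessions), len(conditions)), dtype=bool)
    stack = MapStack(mask, subjects, sessions, conditions, values, present)
    flat = mask.indices
    truth = PhantomTruth(
        true_icc=(s2b.ravel()[flat] / (s2b.ravel()[flat] + s2w.ravel()[flat])),
        sigma2_between=s2b.ravel()[flat],
        sigma2_within=s2w.ravel()[flat],
        seed=spec.seed,
    )
    return stack, truth


def _spearman_from_pearson(r: float) -> float:
    """Spearman rho implied by a bivariate-normal Pearson correlation."""
    return 6.0 / math.pi * math.asin(r / 2.0)


def generate_condition_stack(
    spec: PhantomSpec,
    conditions: tuple[str, ...] | None = None,
    sharing: float = 0.5,
    pattern_scale: float = 1.0,
    differences: dict[str, tuple[str, str]] | None = None,
) -> tuple[MapStack, PhantomTruth]:
    """Multi-condition stack with controlled between-condition sharing.

    The sharing coefficient ``lambda = sharing`` acts on the *stable*
    (reproducible) part of each condition's signal — both the fixed mean
    pattern and the per-subject effect field:

        mu_c      = pattern_scale * (sqrt(l) * C      + sqrt(1-l) * U_c)
        b_{i,c}   = sd_between    * (sqrt(l) * G_i    + sqrt(1-l) * H_{i,c})
        Y[i,s,c]  = mu_c + b_{i,c} + eps[i,s,c],  eps ~ N(0, sigma2_within)

    with C, U_c, G_i, H_{i,c} independent unit-variance white fields.
    Session noise is condition-independent measurement error, so
    subtracting two conditions removes a fraction ``l`` of the shared
    stable variance while the noise adds — the classic difference-score
    attenuation. ``differences`` maps new condition names to
    (minuend, subtrahend) pairs computed by literal subtraction.

    Analytic expectations recorded in the truth (unsmoothed, region-free
    model; P = pattern_scale**2, B = sigma2_between, W = sigma2_within):

    - per-condition spatial test-retest r = (P + B) / (P + B + W)
    - same-session cross-condition Pearson r = l * (P + B) / (P + B + W)
    - difference-map test-retest r =
      (1 - l)(P + B) / ((1 - l)(P + B) + W)
    - voxel-wise true ICC: B / (B + W) per condition,
      (1 - l) B / ((1 - l) B + W) for a difference condition
    """
    if not 0.0 <= sharing <= 1.0:
        raise ValueError(f"sharing must lie in [0, 1], got {sharing}")
    if conditions is None:
        conditions = ("food", "neutral")
    if spec.regions:
        raise ValueError(
            "condition stacks use homogeneous variance components; "
            "regions are not supported here"
        )
    mask = spec.full_mask()
    n, sessions = spec.n_subjects, list(spec.sessions)
    sd_b, sd_w = math.sqrt(spec.sigma2_between), math.sqrt(spec.sigma2_within)
    sq_l, sq_u = math.sqrt(sharing), math.sqrt(1.0 - sharing)

    common = _rng(spec.seed, _TAG_FIELD, 0).standard_normal(spec.shape)
    mus = []
    for c in range(len(conditions)):
        unique = _rng(spec.seed, _TAG_FIELD, 1 + c).standard_normal(spec.shape)
        mus.append(pattern_scale * (sq_l * common + sq_u * unique))

    cond_names = list(conditions)
    values = np.empty((n, len(sessions), len(cond_names), mask.n_voxels))
    for i in range(n):
        g = _rng(spec.seed, _TAG_SUBJECT, i, 0).standard_normal(spec.shape)
        for c, mu in enumerate(mus):
            h = _rng(spec.seed, _TAG_SUBJECT, i, 1 + c).standard_normal(spec.shape)
            b = sd_b * (sq_l * g + sq_u * h)
            for s in range(len(sessions)):
                eps = (
                    _rng(spec.seed, _TAG_SESSION, i, s, c).standard_normal(spec.shape)
                    * sd_w
                )
                vol = _smooth(mu + b + eps, spec.smoothing_sigma)
                if spec.pseudo_t_se is not None:
                    vol = vol / spec.pseudo_t_se
                values[i, s, c] = vol.ravel()[mask.indices]

    if differences:
        for name, (mina, minb) in differences.items():
            ia, ib = cond_names.index(mina), cond_names.index(minb)
            diff = values[:, :, ia, :] - values[:, :, ib, :]
            values = np.concatenate([values, diff[:, :, None, :]], axis=2)
            cond_names.append(name)

    subjects = [f"sub-{i + 1:03d}" for i in range(n)]
    present = np.ones((n, len(sessions), len(cond_names)), dtype=bool)
    stack = MapStack(mask, subjects, sessions, cond_names, values, present)

    p = pattern_scale**2
    b_var, w_var = spec.sigma2_between, spec.sigma2_within
    stable = p + b_var
    retest = stable / (stable + w_var)
    rho_xy = sharing * stable / (stable + w_var)
    diff_retest = (1 - sharing) * stable / ((1 - sharing) * stable + w_var)
    nvox = mask.n_voxels
    truth = PhantomTruth(
        true_icc=np.full(nvox, b_var / (b_var + w_var)),
        sigma2_between=np.full(nvox, b_var),
        sigma2_within=np.full(nvox, w_var),
        sharing=sharing,
        pattern_scale=pattern_scale,
        expected_rho_pearson=rho_xy,
        expected_rho_spearman=_spearman_from_pearson(rho_xy),
        expected_retest_r=retest,
        expected_difference_retest_r=diff_retest,
        true_difference_icc=(1 - sharing) * b_var
        / ((1 - sharing) * b_var + w_var),
        seed=spec.seed,
    )
    return stack, truth


def generate_ratings(
    n_subjects: int = 11,
    session_effects: tuple[float, ...] = (45.195, 18.550, 32.450),
    subject_sd: float = 15.0,
    noise_sd: float = 5.0,
    seed: int = 0,
    sessions: tuple[str, ...] | None = None,
    neutral_mean: float = 25.0,
    baseline_sd: float = 5.0,
    n_food_blocks: int = 18,
    n_neutral_blocks: int = 12,
) -> RatingsTable:
    """Synthetic in-scanner craving ratings with a session (time) effect.

    Per subject and session, ``n_food_blocks`` food and ``n_neutral_blocks``
    neutral block ratings are drawn; the expected food-minus-neutral
    contrast in session s equals ``session_effects[s]``. ``subject_sd``
    scales a stable per-subject contrast effect, ``baseline_sd`` a
    per-subject baseline shift common to both conditions (it cancels in
    the contrast), and ``noise_sd`` the per-block rating noise. Ratings
    are clipped to the 0-100 visual-analogue range (with the default
    parameters clipping is rare).

    Defaults mirror an 11-subject, three-session block-design study with
    a large craving contrast at baseline that drops after an intervention
    and partially rebounds.
    """
    if subject_sd < 0 or noise_sd < 0 or baseline_sd < 0:
        raise ValueError("SDs must be non-negative")
    if sessions is None:
        sessions = tuple(f"T{i}" for i in range(len(session_effects)))
    if len(sessions) != len(session_effects):
        raise ValueError("sessions and session_effects lengths differ")
    rows = []
    for i in range(n_subjects):
        rng = _rng(seed, _TAG_SUBJECT, i)
        baseline = rng.normal(0.0, baseline_sd) if baseline_sd else 0.0
        contrast_effect = rng.normal(0.0, subject_sd) if subject_sd else 0.0
        for s, sess in enumerate(sessions):
            rng_s = _rng(seed, _TAG_SESSION, i, s)
            neutral_level = neutral_mean + baseline
            food_level = neutral_level + session_effects[s] + contrast_effect
            for _ in range(n_food_blocks):
                noise = rng_s.normal(0.0, noise_sd) if noise_sd else 0.0
                rows.append((f"sub-{i + 1:03d}", sess, "food", food_level + noise))
            for _ in range(n_neutral_blocks):
                noise = rng_s.normal(0.0, noise_sd) if noise_sd else 0.0
                rows.append((f"sub-{i + 1:03d}", sess, "neutral", neutral_level + noise))
    frame = pd.DataFrame(rows, columns=["subject", "session", "condition", "rating"])
    frame["rating"] = frame["rating"].clip(0.0, 100.0)
    return RatingsTable(frame)


def write_bundle(
    out_dir: str | Path,
    spec: PhantomSpec,
    sharing: float | None = None,
    pattern_scale: float = 1.0,
    differences: dict[str, tuple[str, str]] | None = None,
    ratings: bool = True,
) -> Path:
    """Emit a phantom as an on-disk study bundle.

    Writes per-cell NIfTI volumes, a manifest TSV, the mask, a toy atlas
    whose labels are the phantom regions (or a single whole-grid region),
    a ratings TSV, and the ground truth as JSON. Returns the directory.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if sharing is None:
        stack, truth = generate_stack(spec)
    else:
        stack, truth = generate_condition_stack(
            spec, conditions=spec.conditions, sharing=sharing,
            pattern_scale=pattern_scale, differences=differences,
        )
    mask = stack.mask
    write_map(np.ones(mask.n_voxels), mask, out_dir / "mask.nii.gz")

    rows = []
    vol_dir = out_dir / "maps"
    for subj in stack.subjects:
        for sess in stack.sessions:
            for cond in stack.conditions:
                path = vol_dir / f"{subj}_{sess}_{cond}.nii.gz"
                write_map(stack.get(subj, sess, cond), mask, path)
                rows.append((subj, sess, cond, str(path)))
    pd.DataFrame(rows, columns=["subject", "session", "condition", "path"]).to_csv(
        out_dir / "manifest.tsv", sep="\t", index=False
    )

    labels = np.zeros(spec.shape, dtype=np.int16)
    lut = []
    if spec.regions:
        for idx, region in enumerate(spec.regions, start=1):
            labels[region.voxel_mask(spec.shape)] = idx
            lut.append((idx, region.name))
    else:
        labels[:] = 1
        lut.append((1, "whole_grid"))
    import nibabel as nib

    nib.save(
        nib.Nifti1Image(labels.astype(np.int16), mask.grid.affine),
        str(out_dir / "atlas.nii.gz"),
    )
    pd.DataFrame(lut, columns=["label", "name"]).to_csv(
        out_dir / "atlas_lut.tsv", sep="\t", index=False
    )

    if ratings:
        table = generate_ratings(n_subjects=spec.n_subjects, seed=spec.seed)
        table.frame.to_csv(out_dir / "ratings.tsv", sep="\t", index=False)

    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth.summary(), fh, indent=2)
    return out_dir
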