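"""Seeded synthetic cohorts of regional GMV distributions.

This module emulates the *inputs* of the morphometric-network analysis — not
MRI images. Each synthetic subject carries, for each of the 90 atlas regions,
a sample of voxel-wise gray-matter-volume values, together with covariates
(age, sex, education, total intracranial volume), a group label (two patient
groups and a control group) and five cognitive scores.

Generative model
----------------
Region r of subject s draws voxels from a scaled Beta distribution: bounded
support like tissue-probability-derived modulated GMV, never negative. The
Beta mean is

    mu_sr = profile_r + loading_r * z_s[factor(r)] + eta_sr,

where ``profile_r`` is a fixed per-region central value in (0, 1) — a smooth
anatomical gradient shared by left/right homologues — ``z_s`` are 5 shared
latent factors inducing between-region correlation (regions load on one
factor each, in contiguous blocks of homologue pairs), and ``eta_sr`` is
idiosyncratic noise. Nearby-profile regions overlap strongly, so thresholded
histogram-intersection networks are clustered, lattice-like and small-world
rather than random.

Patient groups receive a *homogenization* effect e in [0, 1] with two
coordinated components, both scaled by e:

* module tightening — region means shrink toward their latent-module mean,
  ``mu_sr <- m_block + (1 - tau * e) * (mu_sr - m_block)``, collapsing each
  module toward a common GMV level (local specialization: neighbor
  neighborhoods become denser);
* long-range co-alteration — ``round(e * n_clusters)`` small region cliques
  per subject (members drawn across the whole brain, consecutive cliques
  sharing a member) replace a fraction of their voxels with draws from a
  shared cluster-level distribution, so distant region pairs acquire high
  histogram overlap (diffuse shared pathology creating shortcut edges).

Together these raise inter-region histogram similarity and reproduce the
patient contrast the analysis is designed to detect: higher global and local
efficiency with shorter characteristic path lengths at matched sparsity. A
per-group *regional* effect additionally pulls designated regions toward
(factor > 1) or away from (factor < 1) the subject mean, perturbing their
nodal betweenness centrality.

Cognitive scores are Gaussian with per-group means/SDs; the SDMT score can be
coupled to a subject's measured network efficiency (standardized within
group) with a configured correlation — see ``attach_cognitive_scores``.

Determinism: one global seed expands into per-subject substreams through
``numpy.random.SeedSequence`` spawn keys, so outputs are independent of
generation order and bit-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .regions import aal90_table

__all__ = [
    "CohortDesign",
    "SubjectMorphometry",
    "default_design",
    "generate_cohort",
    "generate_cognitive_scores",
    "attach_cognitive_scores",
    "write_cohort",
    "read_cohort",
    "SCORE_NAMES",
    "GROUPS",
]

GROUPS = ("CSVD-c", "CSVD-n", "control")
SCORE_NAMES = ("MoCA", "AVLT", "SDMT", "SCWT", "TMT_BA")

# Table-style cognitive score model: score -> group -> (mean, sd)
_DEFAULT_COGNITION = {
    "MoCA": {"CSVD-c": (24.34, 3.05), "CSVD-n": (25.23, 3.65), "control": (26.51, 3.58)},
    "AVLT": {"CSVD-c": (55.81, 14.87), "CSVD-n": (60.37, 11.31), "control": (64.51, 11.89)},
    "SDMT": {"CSVD-c": (27.43, 12.31), "CSVD-n": (31.32, 11.94), "control": (40.01, 13.37)},
    "SCWT": {"CSVD-c": (169.15, 58.97), "CSVD-n": (151.10, 45.11), "control": (133.32, 30.52)},
    "TMT_BA": {"CSVD-c": (152.51, 97.74), "CSVD-n": (130.64, 101.03), "control": (106.00, 80.72)},
}

# correlation between (group-standardized) Eglob and SDMT; negative in
# patients, absent in controls
_DEFAULT_COUPLING = {"CSVD-c": -0.45, "CSVD-n": -0.40, "control": 0.0}


def _default_profile(n_regions: int = 90) -> np.ndarray:
    """Fixed per-region Beta-mean profile: a smooth gradient over homologue
    pairs, spanning 0.28..0.72 so all Beta means stay well inside (0, 1)."""
    n_pairs = (n_regions + 1) // 2
    per_pair = np.linspace(0.28, 0.72, n_pairs)
    return np.repeat(per_pair, 2)[:n_regions]


def _default_factor_assignment(n_regions: int, latent_dims: int) -> np.ndarray:
    """Assign homologue pairs to latent factors in contiguous blocks."""
    pair = np.arange(n_regions) // 2
    n_pairs = n_regions // 2 + n_regions % 2
    block = (pair * latent_dims) // n_pairs
    return block.astype(int)


@dataclass
class CohortDesign:
    """Full parameterization of a synthetic cohort.

    ``homogenization_effect`` must be 0 for the control group. The regional
    effect maps a group to a list of ``(region_abbreviations, factor)`` pairs;
    factor > 1 pulls those regions toward the subject's mean GMV level
    (raising their connectivity and betweenness), factor < 1 pushes them away.
    """

    group_sizes: dict = field(default_factory=lambda: {
        "CSVD-c": 49, "CSVD-n": 121, "control": 74})
    n_regions: int = 90
    voxels_per_region: tuple = (200, 2000)
    region_mean_profile: np.ndarray | None = None
    region_spread: float = 0.07
    latent_dims: int = 5
    latent_scale: float = 0.015
    idiosyncratic_sd: float = 0.01
    homogenization_effect: dict = field(default_factory=lambda: {
        "CSVD-c": 1.0, "CSVD-n": 0.93, "control": 0.0})
    module_tightening: float = 0.95
    n_coalteration_clusters: int = 22
    cluster_size: int = 4
    cluster_mix: float = 0.55
    regional_bc_effect: dict = field(default_factory=lambda: {
        "CSVD-c": [(("ACG.L", "ACG.R", "MTG.R", "SPG.L"), 1.6),
                   (("SFGdor.L",), 0.7)],
        "CSVD-n": [(("IPL.L", "INS.L"), 1.4),
                   (("FFG.L", "IFGoperc.R", "CAU.R"), 0.75)],
    })
    covariate_model: dict = field(default_factory=lambda: {
        "age": (62.5, 8.3, 45.0, 80.0),
        "education": (12.0, 3.3, 7.0, 22.0),
        "tiv": (1.59, 0.15, 1.0, 2.3),
        "sex_female_rate": 0.48,
    })
    cognition_model: dict = field(default_factory=lambda: dict(_DEFAULT_COGNITION))
    sdmt_coupling: dict = field(default_factory=lambda: dict(_DEFAULT_COUPLING))
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.group_sizes:
            raise ValueError("group_sizes must name at least one group")
        for g, n in self.group_sizes.items():
            if int(n) < 2:
                raise ValueError(f"group {g!r}: size must be >= 2, got {n}")
        lo, hi = self.voxels_per_region
        if not (1 <= lo <= hi):
            raise ValueError("voxels_per_region must be a valid (low, high) range")
        if self.region_spread <= 0 or self.idiosyncratic_sd < 0:
            raise ValueError("spreads must be positive")
        for g, e in self.homogenization_effect.items():
            if not 0 <= e <= 1:
                raise ValueError(f"homogenization_effect[{g!r}] outside [0, 1]")
        if not 0 <= self.module_tightening < 1:
            raise ValueError("module_tightening must lie in [0, 1)")
        if self.n_coalteration_clusters < 0 or self.cluster_size < 2:
            raise ValueError("bad co-alteration cluster settings")
        if not 0 <= self.cluster_mix <= 1:
            raise ValueError("cluster_mix must lie in [0, 1]")
        if self.cluster_size > self.n_regions:
            raise ValueError("cluster_size exceeds the region count")
        if self.homogenization_effect.get("control", 0.0) != 0.0:
            raise ValueError("homogenization_effect must be 0 for the control group")
        for g, entries in self.regional_bc_effect.items():
            for regions, factor in entries:
                if len(regions) == 0:
                    raise ValueError(
                        f"regional effect for group {g!r} declares an empty region set")
                if factor <= 0:
                    raise ValueError("regional effect factor must be positive")
        for score, per_group in self.cognition_model.items():
            for g, (m, s) in per_group.items():
                if not (np.isfinite(m) and np.isfinite(s) and s >= 0):
                    raise ValueError(f"bad cognition model for {score}/{g}")
            missing = set(self.group_sizes) - set(per_group)
            if missing:
                raise ValueError(
                    f"cognition model for {score} lacks group(s) {sorted(missing)}")
        for g, rho in self.sdmt_coupling.items():
            if not np.isfinite(rho) or abs(rho) > 1:
                raise ValueError(f"sdmt_coupling[{g!r}] must lie in [-1, 1]")

    def profile(self) -> np.ndarray:
        if self.region_mean_profile is not None:
            p = np.asarray(self.region_mean_profile, dtype=float)
            if p.shape != (self.n_regions,):
                raise ValueError("region_mean_profile must have one entry per region")
            return p
        return _default_profile(self.n_regions)

    def to_json(self, path=None) -> str:
        d = dataclasses.asdict(self)
        if d["region_mean_profile"] is not None:
            d["region_mean_profile"] = list(map(float, d["region_mean_profile"]))
        d["voxels_per_region"] = list(d["voxels_per_region"])
        d["regional_bc_effect"] = {
            g: [[list(regions), factor] for regions, factor in entries]
            for g, entries in d["regional_bc_effect"].items()}
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "CohortDesign":
        if hasattr(source, "read"):
            d = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                d = json.loads(text)
            else:
                with open(text, encoding="utf-8") as fh:
                    d = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown design fields: {sorted(unknown)}")
        if d.get("region_mean_profile") is not None:
            d["region_mean_profile"] = np.asarray(d["region_mean_profile"], float)
        if "voxels_per_region" in d:
            d["voxels_per_region"] = tuple(d["voxels_per_region"])
        if "regional_bc_effect" in d:
            d["regional_bc_effect"] = {
                g: [(tuple(regions), float(factor)) for regions, factor in entries]
                for g, entries in d["regional_bc_effect"].items()}
        if "covariate_model" in d:
            d["covariate_model"] = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["covariate_model"].items()}
        if "cognition_model" in d:
            d["cognition_model"] = {
                score: {g: tuple(ms) for g, ms in per_group.items()}
                for score, per_group in d["cognition_model"].items()}
        return cls(**d)


def default_design(**overrides) -> CohortDesign:
    """The default study design; keyword overrides replace single fields."""
    return dataclasses.replace(CohortDesign(), **overrides) if overrides else CohortDesign()


@dataclass
class SubjectMorphometry:
    """One subject's per-region GMV samples plus covariates and group label."""

    subject_id: str
    group: str
    region_values: list  # one 1-D non-negative array per region
    age: float
    sex: int  # 1 = female
    education: float
    tiv: float
    cognitive_scores: dict

    def validate(self) -> None:
        if self.tiv <= 0:
            raise ValueError(f"{self.subject_id}: TIV must be positive")
        for r, vals in enumerate(self.region_values, start=1):
            v = np.asarray(vals, dtype=float)
            if v.size < 2:
                raise ValueError(f"{self.subject_id}: region {r} has < 2 values")
            if not np.isfinite(v).all() or (v < 0).any():
                raise ValueError(
                    f"{self.subject_id}: region {r} has non-finite or negative values")


def _subject_rng(seed: int, group_idx: int, subj_idx: int, stream: int):
    ss = np.random.SeedSequence(entropy=int(seed),
                                spawn_key=(group_idx, subj_idx, stream))
    return np.random.Generator(np.random.PCG64(ss))


def _region_indices(abbrevs, table) -> np.ndarray:
    lookup = {a: i for i, a in zip(table.index, table["abbreviation"])}
    idx = []
    for a in abbrevs:
        if a not in lookup:
            raise ValueError(f"unknown region abbreviation in design: {a!r}")
        idx.append(lookup[a] - 1)
    return np.array(idx, dtype=int)


def generate_cohort(design: CohortDesign) -> list[SubjectMorphometry]:
    """Generate the full cohort described by a design.

    Returns exactly ``sum(group_sizes.values())`` subjects. Identical designs
    (including seed) produce bit-identical cohorts. Cognitive scores here use
    zero efficiency coupling (the coupling needs the measured network
    efficiency; see :func:`attach_cognitive_scores`).
    """
    design.validate()
    profile = design.profile()
    factor_of = _default_factor_assignment(design.n_regions, design.latent_dims)
    table = aal90_table() if design.n_regions == 90 else None
    regional = {}
    for g, entries in design.regional_bc_effect.items():
        if table is None:
            continue  # regional effects are defined on the 90-region atlas
        regional[g] = [(_region_indices(regions, table), float(f))
                       for regions, f in entries]
    cohort = []
    for gi, (group, size) in enumerate(sorted(design.group_sizes.items())):
        e = float(design.homogenization_effect.get(group, 0.0))
        for si in range(int(size)):
            rng = _subject_rng(design.seed, gi, si, stream=0)
            subject = _generate_subject(design, group, gi, si, e,
                                        regional.get(group, []), profile,
                                        factor_of, rng)
            cohort.append(subject)
    return cohort


def _generate_subject(design, group, gi, si, homog, regional, profile,
                      factor_of, rng) -> SubjectMorphometry:
    z = rng.standard_normal(design.latent_dims) * design.latent_scale
    eta = rng.standard_normal(design.n_regions) * design.idiosyncratic_sd
    mu = np.clip(profile + z[factor_of] + eta, 0.03, 0.97)
    if homog > 0:
        # module tightening: shrink region means toward their latent-module mean
        block_mean = np.array([mu[factor_of == b].mean()
                               for b in range(design.latent_dims)])
        shrink = 1.0 - design.module_tightening * homog
        mu = block_mean[factor_of] + shrink * (mu - block_mean[factor_of])
    m = mu.mean()
    for idx, factor in regional:
        mu[idx] = m + (mu[idx] - m) / factor
    mu = np.clip(mu, 0.02, 0.98)

    # covariates
    cm = design.covariate_model
    age = float(np.clip(rng.normal(cm["age"][0], cm["age"][1]),
                        cm["age"][2], cm["age"][3]))
    education = float(np.clip(rng.normal(cm["education"][0], cm["education"][1]),
                              cm["education"][2], cm["education"][3]))
    tiv = float(np.clip(rng.normal(cm["tiv"][0], cm["tiv"][1]),
                        cm["tiv"][2], cm["tiv"][3]))
    sex = int(rng.random() < cm["sex_female_rate"])

    lo, hi = design.voxels_per_region
    n_vox = rng.integers(int(lo), int(hi) + 1, size=design.n_regions)
    var = design.region_spread ** 2
    nus = np.maximum(mu * (1 - mu) / var - 1.0, 2.0)
    values = [rng.beta(mu[r] * nus[r], (1 - mu[r]) * nus[r], int(n_vox[r]))
              for r in range(design.n_regions)]

    # long-range co-alteration: chained region cliques share a voxel fraction
    n_clusters = int(round(design.n_coalteration_clusters * homog))
    if n_clusters > 0:
        all_regions = np.arange(design.n_regions)
        prev = None
        for _ in range(n_clusters):
            if prev is None:
                members = rng.choice(all_regions, design.cluster_size,
                                     replace=False)
            else:
                first = prev[int(rng.integers(prev.size))]
                rest = rng.choice(np.setdiff1d(all_regions, [first]),
                                  design.cluster_size - 1, replace=False)
                members = np.concatenate([[first], rest])
            mc = float(mu[members].mean())
            nuc = max(mc * (1 - mc) / var - 1.0, 2.0)
            for r in members:
                k = int(design.cluster_mix * values[r].size)
                values[r][:k] = rng.beta(mc * nuc, (1 - mc) * nuc, k)
            prev = members
    values = [v * tiv for v in values]

    score_rng = _subject_rng(design.seed, gi, si, stream=1)
    scores = generate_cognitive_scores(0.0, group, design, score_rng)
    return SubjectMorphometry(
        subject_id=f"{group}-{si + 1:03d}", group=group, region_values=values,
        age=age, sex=sex, education=education, tiv=tiv, cognitive_scores=scores)


def generate_cognitive_scores(subject_efficiency: float, group: str,
                              design: CohortDesign, rng) -> dict:
    """Draw the five cognitive scores for one subject.

    ``subject_efficiency`` is the subject's network efficiency standardized
    within group (z-score). The SDMT score mixes it in with the configured
    correlation rho: ``mean + sd * (rho * z + sqrt(1 - rho^2) * noise)``, so
    designed couplings are recovered as sample correlations. MoCA is capped at
    30 (screening-test ceiling); timed scores are kept positive.
    """
    if group not in design.cognition_model.get("MoCA", {}):
        raise ValueError(f"unknown group {group!r} in cognition model")
    scores = {}
    for name in SCORE_NAMES:
        mean, sd = design.cognition_model[name][group]
        eps = rng.standard_normal()
        if name == "SDMT":
            rho = float(design.sdmt_coupling.get(group, 0.0))
            value = mean + sd * (rho * subject_efficiency
                                 + np.sqrt(1 - rho ** 2) * eps)
        else:
            value = mean + sd * eps
        if name == "MoCA":
            value = float(np.clip(value, 0.0, 30.0))
        else:
            value = float(max(value, 1.0))
        scores[name] = value
    return scores


def attach_cognitive_scores(cohort: list[SubjectMorphometry],
                            efficiency: dict, design: CohortDesign) -> None:
    """Regenerate scores in place, coupling SDMT to measured efficiency.

    ``efficiency`` maps subject_id to the subject's global-efficiency AUC (or
    any efficiency summary); it is standardized within each group before being
    passed to :func:`generate_cognitive_scores`. Seeded from the design, so
    the operation is reproducible.
    """
    groups = sorted({s.group for s in cohort})
    zscores = {}
    for g in groups:
        ids = [s.subject_id for s in cohort if s.group == g]
        vals = np.array([float(efficiency[i]) for i in ids])
        sd = vals.std(ddof=1)
        centered = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
        zscores.update(dict(zip(ids, centered)))
    group_index = {g: gi for gi, g in enumerate(sorted(design.group_sizes))}
    counters = {g: 0 for g in group_index}
    for subject in cohort:
        gi = group_index[subject.group]
        si = counters[subject.group]
        counters[subject.group] += 1
        rng = _subject_rng(design.seed, gi, si, stream=1)
        subject.cognitive_scores = generate_cognitive_scores(
            float(zscores[subject.subject_id]), subject.group, design, rng)


# ---------------------------------------------------------------------------
# cohort serialization: one UTF-8 TSV file, two sections


_SUBJECT_COLS = ("subject_id", "group", "age", "sex", "education", "tiv",
                 *SCORE_NAMES)


def write_cohort(cohort: list[SubjectMorphometry], path) -> None:
    """Write a cohort to a tab-separated text file.

    Layout: a ``[subjects]`` section with one covariate/score row per subject,
    then a ``[region_values]`` section with one row per (subject, region);
    voxel values are space-separated full-precision floats.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# gmnet cohort v1\n")
        fh.write("[subjects]\n")
        fh.write("\t".join(_SUBJECT_COLS) + "\n")
        for s in cohort:
            row = [s.subject_id, s.group, repr(float(s.age)), str(int(s.sex)),
                   repr(float(s.education)), repr(float(s.tiv))]
            row += [repr(float(s.cognitive_scores[k])) for k in SCORE_NAMES]
            fh.write("\t".join(row) + "\n")
        fh.write("[region_values]\n")
        fh.write("subject_id\tregion_index\tvalues\n")
        for s in cohort:
            for r, vals in enumerate(s.region_values, start=1):
                joined = " ".join(repr(float(v)) for v in np.asarray(vals))
                fh.write(f"{s.subject_id}\t{r}\t{joined}\n")


class CohortParseError(ValueError):
    """Raised with the offending line number when a cohort file is malformed."""


def read_cohort(path) -> list[SubjectMorphometry]:
    """Read a cohort file written by :func:`write_cohort` (round-trip exact)."""
    subjects: dict[str, SubjectMorphometry] = {}
    region_values: dict[str, dict[int, np.ndarray]] = {}
    section = None
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line in ("[subjects]", "[region_values]"):
                section, header_seen = line, False
                continue
            if section is None:
                raise CohortParseError(f"line {lineno}: content before any section")
            fields = line.split("\t")
            if not header_seen:
                header_seen = True
                expected = (list(_SUBJECT_COLS) if section == "[subjects]"
                            else ["subject_id", "region_index", "values"])
                if fields != expected:
                    raise CohortParseError(
                        f"line {lineno}: bad {section} header {fields!r}")
                continue
            try:
                if section == "[subjects]":
                    if len(fields) != len(_SUBJECT_COLS):
                        raise ValueError(f"expected {len(_SUBJECT_COLS)} columns")
                    sid, group = fields[0], fields[1]
                    subjects[sid] = SubjectMorphometry(
                        subject_id=sid, group=group, region_values=[],
                        age=float(fields[2]), sex=int(fields[3]),
                        education=float(fields[4]), tiv=float(fields[5]),
                        cognitive_scores={k: float(v) for k, v in
                                          zip(SCORE_NAMES, fields[6:])})
                else:
                    if len(fields) != 3:
                        raise ValueError("expected 3 columns")
                    sid, r = fields[0], int(fields[1])
                    vals = np.array([float(x) for x in fields[2].split()])
                    region_values.setdefault(sid, {})[r] = vals
            except ValueError as err:
                raise CohortParseError(f"line {lineno}: {err}") from err
    if not subjects:
        raise CohortParseError("no [subjects] section found")
    n_regions = max((max(d) for d in region_values.values()), default=0)
    cohort = []
    for sid, s in subjects.items():
        per_region = region_values.get(sid, {})
        missing = [r for r in range(1, n_regions + 1) if r not in per_region]
        if missing:
            raise CohortParseError(
                f"subject {sid}: missing region value rows for region(s) "
                f"{missing[:5]}{'...' if len(missing) > 5 else ''}")
        s.region_values = [per_region[r] for r in range(1, n_regions + 1)]
        s.validate()
        cohort.append(s)
    return cohort
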