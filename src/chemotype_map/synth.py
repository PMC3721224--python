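"""Synthetic metabogenomic studies with known ground truth.

The generator emulates the structure of the motivating survey — seven sites x
three replicates, 43 recurring GC/MS features, five chemogroups nested in two
DNA-barcode phylogroups, two single-sample chemogroup exceptions and one
cross-marker phylogroup conflict — so every pipeline stage can be exercised
and validated without the (undeposited) raw data.

Chemistry: each chemogroup has a template profile over the feature pool
(exclusive high-intensity features plus lower-intensity features shared with
neighbouring groups, which sets the between-group Bray-Curtis similarity).
Replicates multiply template intensities by lognormal noise and jitter
retention times; every feature carries a halogen composition whose theoretical
isotope envelope is attached to the peak.  Genetics: per marker, two clade
ancestors are separated by a fixed number of substitutions and leaves are
perturbed within a small within-clade bound (Jukes-Cantor-style uniform
substitutions), so the maximum pairwise p-distance respects the configured
divergence ceiling.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import study
from .chemotype import bray_curtis
from .features import Peak, SampleRun, write_peak_table
from .isotope import theoretical_envelope

__all__ = [
    "SynthConfigError",
    "SynthConfig",
    "GroundTruth",
    "SimulatedStudy",
    "simulate_profiles",
    "simulate_peak_tables",
    "simulate_sequences",
    "simulate_study",
]

_BASES = np.array(list("ACGT"))


class SynthConfigError(ValueError):
    """Raised when generator targets are infeasible or inconsistent."""


def _default_site_chemogroups() -> dict[str, str]:
    return dict(study._SITE_CHEMOGROUP)


def _default_cg_phylogroups() -> dict[str, str]:
    return study.chemogroup_to_phylogroup()


@dataclass
class SynthConfig:
    """Study-design knobs for the generator; defaults mirror the survey."""

    n_sites: int = 7
    replicates_per_site: int = 3
    n_chemogroups: int = 5
    n_phylogroups: int = 2
    feature_pool_size: int = 43
    #: fraction of the feature pool shared between neighbouring chemogroups
    shared_feature_fraction: float = 0.2
    exclusive_intensity_range: tuple[float, float] = (30.0, 100.0)
    shared_intensity_range: tuple[float, float] = (15.0, 25.0)
    within_similarity_target: float = 70.0
    between_similarity_target: float = 40.0
    intensity_sigma: float = 0.25
    rt_jitter_sd_min: float = 0.02
    rt_window: tuple[float, float] = (10.0, 30.0)
    max_halogens_per_feature: int = 8
    seq_length: dict = field(default_factory=lambda: {"cox1": 660, "rbcL": 890})
    within_clade_p: float = 0.005
    between_clade_p: dict = field(default_factory=lambda: {"cox1": 0.021, "rbcL": 0.011})
    site_chemogroups: dict = field(default_factory=_default_site_chemogroups)
    chemogroup_phylogroups: dict = field(default_factory=_default_cg_phylogroups)
    chemo_exceptions: dict = field(default_factory=lambda: {"1B": "CG2", "6C": "CG5"})
    marker_exceptions: dict = field(default_factory=lambda: {"rbcL": {"6A": "A"}})
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sites", "replicates_per_site", "n_chemogroups",
                     "n_phylogroups", "feature_pool_size"):
            if getattr(self, name) < 1:
                raise SynthConfigError(f"{name} must be positive")
        if not 0 <= self.shared_feature_fraction < 1:
            raise SynthConfigError("shared_feature_fraction must lie in [0, 1)")
        if self.within_clade_p < 0 or any(p <= 0 or p >= 0.75 for p in self.between_clade_p.values()):
            raise SynthConfigError("divergences must lie in [0, 0.75)")
        if self.n_chemogroups > self.feature_pool_size:
            raise SynthConfigError("need at least one feature per chemogroup")

    def sample_ids(self) -> list[str]:
        reps = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"[: self.replicates_per_site]
        return [f"{s}{r}" for s in range(1, self.n_sites + 1) for r in reps]

    def chemogroup_of(self, sample_id: str) -> str:
        if sample_id in self.chemo_exceptions:
            return self.chemo_exceptions[sample_id]
        site = sample_id[:-1]
        if site in self.site_chemogroups:
            return self.site_chemogroups[site]
        return f"CG{(int(site) - 1) % self.n_chemogroups + 1}"

    def phylogroup_of(self, sample_id: str, marker: str) -> str:
        exc = self.marker_exceptions.get(marker, {})
        if sample_id in exc:
            return exc[sample_id]
        return self.chemogroup_phylogroups[self.chemogroup_of(sample_id)]


@dataclass
class GroundTruth:
    """Generator-side truth emitted alongside the data files."""

    samples: dict
    features: dict
    realized: dict

    def chemogroups(self) -> dict[str, str]:
        return {sid: rec["chemogroup"] for sid, rec in self.samples.items()}

    def phylogroups(self, marker: str) -> dict[str, str]:
        return {sid: rec["phylogroup"][marker] for sid, rec in self.samples.items()}

    def sites(self) -> dict[str, str]:
        return {sid: rec["site"] for sid, rec in self.samples.items()}

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class SimulatedStudy:
    config: SynthConfig
    runs: list
    sequences: dict
    design: pd.DataFrame
    templates: dict
    ground_truth: GroundTruth


def _feature_pool(config: SynthConfig, rng: np.random.Generator) -> list[dict]:
    lo, hi = config.rt_window
    margin = 0.5
    rts = np.linspace(lo + margin, hi - margin, config.feature_pool_size)
    masses = rng.choice(np.arange(250, 520), size=config.feature_pool_size, replace=False)
    pool = []
    for i in range(config.feature_pool_size):
        total = int(rng.integers(2, min(config.max_halogens_per_feature, 6) + 1))
        n_br = int(rng.integers(0, total + 1))
        pool.append(
            {
                "rt": float(rts[i]),
                "base_mass": int(masses[i]),
                "n_cl": total - n_br,
                "n_br": n_br,
            }
        )
    return pool


def simulate_profiles(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[list[dict], dict[str, dict[int, float]], dict]:
    """Chemogroup template profiles over a common feature pool.

    Returns (feature pool, templates mapping chemogroup -> {feature index:
    intensity}, realized-similarity summary).  The shared-feature overlap is
    sized so the expected between-group Bray-Curtis similarity stays at or
    below the configured target while within-group similarity (template plus
    replicate noise) stays at or above its target; violations raise
    :class:`SynthConfigError`.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    pool = _feature_pool(config, rng)
    k = config.n_chemogroups
    n_shared = int(round(config.feature_pool_size * config.shared_feature_fraction))
    if config.feature_pool_size - n_shared < k:
        raise SynthConfigError("shared_feature_fraction leaves too few exclusive features")
    indices = list(range(config.feature_pool_size))
    shared = indices[-n_shared:] if n_shared else []
    exclusive = indices[: config.feature_pool_size - n_shared]

    groups = [f"CG{i + 1}" for i in range(k)]
    templates: dict[str, dict[int, float]] = {g: {} for g in groups}
    for pos, idx in enumerate(exclusive):
        g = groups[pos % k]
        lo, hi = config.exclusive_intensity_range
        templates[g][idx] = float(rng.uniform(lo, hi))
    for pos, idx in enumerate(shared):
        lo, hi = config.shared_intensity_range
        val = float(rng.uniform(lo, hi))
        for g in (groups[pos % k], groups[(pos + 1) % k]):
            templates[g][idx] = val
    # anchor each template's base peak at exactly 100
    for g in groups:
        top = max(templates[g].values())
        templates[g] = {i: 100.0 * v / top for i, v in templates[g].items()}

    full = {
        g: np.array([templates[g].get(i, 0.0) for i in indices]) for g in groups
    }
    between = [
        100.0 * (1.0 - bray_curtis(full[a], full[b]))
        for ai, a in enumerate(groups)
        for b in groups[ai + 1 :]
    ]
    # Monte-Carlo estimate of within-group replicate similarity under noise
    within = []
    for g in groups:
        sims = []
        for _ in range(20):
            x = full[g] * rng.lognormal(0.0, config.intensity_sigma, full[g].size)
            y = full[g] * rng.lognormal(0.0, config.intensity_sigma, full[g].size)
            sims.append(100.0 * (1.0 - bray_curtis(x, y)))
        within.append(float(np.mean(sims)))
    realized = {
        "between_similarity_max_pct": max(between) if between else 0.0,
        "between_similarity_mean_pct": float(np.mean(between)) if between else 0.0,
        "within_similarity_min_pct": min(within),
    }
    if between and max(between) > config.between_similarity_target:
        raise SynthConfigError(
            f"between-group similarity {max(between):.1f}% exceeds target "
            f"{config.between_similarity_target}%; reduce shared_feature_fraction"
        )
    if min(within) < config.within_similarity_target:
        raise SynthConfigError(
            f"within-group similarity {min(within):.1f}% below target "
            f"{config.within_similarity_target}%; reduce intensity_sigma"
        )
    return pool, templates, realized


def simulate_peak_tables(
    config: SynthConfig,
    pool: list[dict],
    templates: dict[str, dict[int, float]],
    rng: np.random.Generator,
) -> list[SampleRun]:
    """Per-sample peak tables: noisy template draws with isotope envelopes."""
    runs = []
    for sid in config.sample_ids():
        template = templates[config.chemogroup_of(sid)]
        scale = 1e4 * rng.lognormal(0.0, 0.2)
        peaks = []
        for idx, intensity in sorted(template.items()):
            feat = pool[idx]
            height = intensity * rng.lognormal(0.0, config.intensity_sigma) * scale
            rt = feat["rt"] + rng.normal(0.0, config.rt_jitter_sd_min)
            env = theoretical_envelope((feat["n_cl"], feat["n_br"]))
            peaks.append(
                Peak(
                    rt=rt,
                    height=height,
                    base_mass=float(feat["base_mass"]),
                    envelope=[float(a) for a in env.abundances],
                )
            )
        runs.append(SampleRun(sid, peaks))
    return runs


def _mutate(seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    for pos in positions:
        current = out[pos]
        choices = _BASES[_BASES != current]
        out[pos] = rng.choice(choices)
    return out


def simulate_sequences(
    config: SynthConfig, rng: np.random.Generator
) -> dict[str, dict[str, str]]:
    """Two-clade aligned sequences per marker honouring the divergence ceilings.

    The clade ancestors differ at ``floor(L*between) - 2*k_max`` sites and each
    leaf carries at most ``k_max = floor(L*within/2)`` private substitutions,
    so no pair of leaves can exceed the configured between-clade p-distance
    and no within-clade pair the within-clade bound.
    """
    out: dict[str, dict[str, str]] = {}
    letters = [chr(ord("A") + i) for i in range(config.n_phylogroups)]
    for marker, length in config.seq_length.items():
        between = config.between_clade_p.get(marker)
        if between is None:
            raise SynthConfigError(f"no between-clade divergence configured for {marker}")
        k_max = int(math.floor(length * config.within_clade_p / 2))
        m0 = int(math.floor(length * between)) - 2 * k_max
        if m0 < 1:
            raise SynthConfigError(
                f"{marker}: within-clade bound leaves no room for the clade split"
            )
        root = rng.choice(_BASES, size=length)
        ancestors = {letters[0]: root}
        for letter in letters[1:]:
            positions = rng.choice(length, size=m0, replace=False)
            ancestors[letter] = _mutate(root, positions, rng)
        seqs: dict[str, str] = {}
        for sid in config.sample_ids():
            clade = config.phylogroup_of(sid, marker)
            k = int(rng.integers(0, k_max + 1))
            positions = rng.choice(length, size=k, replace=False)
            seqs[sid] = "".join(_mutate(ancestors[clade], positions, rng))
        out[marker] = seqs
    return out


def _design_frame(config: SynthConfig) -> pd.DataFrame:
    if config.n_sites == 7 and config.replicates_per_site == 3:
        return study.study_design()
    rows = [
        {
            "sample_id": sid,
            "site": sid[:-1],
            "depth_m": 10,
            "site_name": f"Site {sid[:-1]}",
        }
        for sid in config.sample_ids()
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def _write_fasta(path: Path, seqs: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def simulate_study(
    config: SynthConfig | None = None,
    out_dir=None,
    seed: int | None = None,
) -> SimulatedStudy:
    """Generate a complete study bundle (peaks, sequences, design, truth).

    With ``out_dir`` set, writes peaks.csv, one FASTA per marker, design.csv
    and ground_truth.json in the formats the pipeline consumes.  The same seed
    and config always produce byte-identical outputs.
    """
    config = SynthConfig() if config is None else config
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)

    pool, templates, realized = simulate_profiles(config, rng)
    runs = simulate_peak_tables(config, pool, templates, rng)
    sequences = simulate_sequences(config, rng)
    design = _design_frame(config)

    markers = list(config.seq_length)
    samples = {
        sid: {
            "site": sid[:-1],
            "chemogroup": config.chemogroup_of(sid),
            "phylogroup": {m: config.phylogroup_of(sid, m) for m in markers},
        }
        for sid in config.sample_ids()
    }
    features = {
        f"rt{feat['rt']:.2f}_m{feat['base_mass']}": {
            "rt": feat["rt"],
            "base_mass": feat["base_mass"],
            "n_cl": feat["n_cl"],
            "n_br": feat["n_br"],
        }
        for feat in pool
    }
    truth = GroundTruth(samples=samples, features=features, realized=realized)
    bundle = SimulatedStudy(
        config=config,
        runs=runs,
        sequences=sequences,
        design=design,
        templates=templates,
        ground_truth=truth,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_peak_table(out / "peaks.csv", runs)
        for marker, seqs in sequences.items():
            _write_fasta(out / f"{marker}.fasta", seqs)
        design.reset_index().to_csv(out / "design.csv", index=False)
        (out / "ground_truth.json").write_text(truth.to_json())
    return bundle
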