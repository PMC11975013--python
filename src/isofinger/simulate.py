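"""Synthetic CSIA-AA studies with known ground truth.

Generates the full measurement layout of a germ-free (GF) versus
conventionalized (CVZ) mouse feeding study: endmember reference profiles
(bacteria / fungi / plants), diet profiles, and consumer tissues under a
single-pool isotopic-incorporation mixing model, so that every downstream
stage of the inference chain can be exercised against a known microbial
contribution fraction.

Generative model
----------------
Each organ replaces a fraction ``p`` of its carbon over the feeding window
(defaults: liver 0.75, kidney 0.60, muscle 0.45, brain 0.30 over 20 days).
The newly incorporated carbon is a linear delta-space mixture of the
experimental diet and, for colonized animals, a gut-microbial EAA pool
with contribution fraction ``f`` (forced to 0 in germ-free animals):

    E[delta_a] = p * ((1 - f) * diet_new_a + f * microbe_a + trophic_a)
                 + (1 - p) * diet_old_a

Analytical replicates add independent Gaussian noise (default SD 0.2
permil, the typical replicate precision of GC-IRMS amino-acid work).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .fingerprint_lda import EndmemberTrainingSet
from .isotope_io import EAA_CODES, validate_measurements, write_measurements

#: Canonical analyte order for the six study EAAs.
DEFAULT_EAAS = EAA_CODES

#: Endmember class mean fingerprints (permil vs VPDB).  Chosen so the three
#: classes separate by several permil on at least two analytes, mirroring
#: published bacteria/fungi/plant reference compilations in overall pattern.
DEFAULT_ENDMEMBER_MEANS: dict[str, dict[str, float]] = {
    "bacteria": {"Ile": -17.0, "Leu": -21.5, "Lys": -14.0,
                 "Phe": -22.0, "Thr": -9.5, "Val": -18.5},
    "fungi": {"Ile": -22.5, "Leu": -26.5, "Lys": -19.5,
              "Phe": -26.5, "Thr": -14.5, "Val": -24.0},
    "plants": {"Ile": -27.5, "Leu": -31.0, "Lys": -25.0,
               "Phe": -29.0, "Thr": -22.5, "Val": -29.0},
}

#: Within-class spread of endmember profiles (permil, per analyte).
DEFAULT_ENDMEMBER_SD = 1.0

DEFAULT_N_PER_ENDMEMBER_CLASS = {"bacteria": 12, "fungi": 9, "plants": 11}

#: Experimental diet protein (C3 dairy casein) delta13C-EAA profile.
DEFAULT_DIET_NEW = {"Ile": -23.5, "Leu": -28.0, "Lys": -21.5,
                    "Phe": -27.5, "Thr": -17.5, "Val": -25.5}

#: Pre-switch chow with C4/marine protein influence: uniformly enriched,
#: so incomplete turnover leaves organ-dependent positive diet offsets.
DEFAULT_DIET_OLD = {a: v + 7.0 for a, v in DEFAULT_DIET_NEW.items()}

#: Gut-microbial EAA pool, bacteria-like by construction.
DEFAULT_MICROBE_SOURCE = dict(DEFAULT_ENDMEMBER_MEANS["bacteria"])

#: Organ carbon replacement fractions over the feeding window.
DEFAULT_TURNOVER = {"liver": 0.75, "kidney": 0.60, "muscle": 0.45, "brain": 0.30}

DEFAULT_NOISE_SD = 0.2
DEFAULT_N_PER_GROUP = 5
DEFAULT_REPLICATES = 2

# Fixed substream codes so adding a component never perturbs earlier draws.
_STREAM = {"endmembers": 11, "diet": 23, "consumers": 37}


class ConfigurationError(ValueError):
    """Simulation configuration violates its invariants."""


def _vector(mapping: Mapping[str, float], eaas: tuple[str, ...], name: str) -> np.ndarray:
    missing = [a for a in eaas if a not in mapping]
    if missing:
        raise ConfigurationError(f"{name} is missing analyte(s): {missing}")
    return np.array([float(mapping[a]) for a in eaas])


@dataclass
class SimulationConfig:
    """Full generative specification of a synthetic GF-vs-CVZ study.

    All delta values are permil vs VPDB.  ``endmember_cov`` entries are
    either a per-analyte SD vector (diagonal covariance) or a full
    symmetric PSD matrix.  ``f_microbial`` maps treatment group to the
    microbial contribution fraction; the GF arm is germ-free by definition
    and must be 0.
    """

    eaa_list: tuple[str, ...] = DEFAULT_EAAS
    endmember_means: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_ENDMEMBER_MEANS.items()})
    endmember_cov: dict = field(default_factory=lambda: {
        k: DEFAULT_ENDMEMBER_SD for k in DEFAULT_ENDMEMBER_MEANS})
    n_per_endmember_class: dict = field(
        default_factory=lambda: dict(DEFAULT_N_PER_ENDMEMBER_CLASS))
    diet_new: dict = field(default_factory=lambda: dict(DEFAULT_DIET_NEW))
    diet_old: dict = field(default_factory=lambda: dict(DEFAULT_DIET_OLD))
    microbe_source: dict = field(default_factory=lambda: dict(DEFAULT_MICROBE_SOURCE))
    turnover: dict = field(default_factory=lambda: dict(DEFAULT_TURNOVER))
    f_microbial: dict = field(default_factory=lambda: {"GF": 0.0, "CVZ": 0.0})
    trophic_offset: dict = field(default_factory=dict)
    noise_sd: float = DEFAULT_NOISE_SD
    n_per_group: int = DEFAULT_N_PER_GROUP
    replicates_per_sample: int = DEFAULT_REPLICATES
    n_diet_samples: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.eaa_list = tuple(self.eaa_list)
        self.validate()

    # -- derived vectors -------------------------------------------------
    def vec_diet_new(self) -> np.ndarray:
        return _vector(self.diet_new, self.eaa_list, "diet_new")

    def vec_diet_old(self) -> np.ndarray:
        return _vector(self.diet_old, self.eaa_list, "diet_old")

    def vec_microbe(self) -> np.ndarray:
        return _vector(self.microbe_source, self.eaa_list, "microbe_source")

    def vec_trophic(self) -> np.ndarray:
        return np.array([float(self.trophic_offset.get(a, 0.0)) for a in self.eaa_list])

    def class_cov(self, cls: str) -> np.ndarray:
        p = len(self.eaa_list)
        spec = self.endmember_cov[cls]
        if np.isscalar(spec):
            return float(spec) ** 2 * np.eye(p)
        arr = np.asarray(spec, dtype=float)
        if arr.ndim == 1:
            if arr.shape != (p,):
                raise ConfigurationError(f"SD vector for {cls} has wrong length")
            return np.diag(arr ** 2)
        if arr.shape != (p, p) or not np.allclose(arr, arr.T):
            raise ConfigurationError(f"covariance for {cls} must be a symmetric {p}x{p} matrix")
        if np.linalg.eigvalsh(arr).min() < -1e-10:
            raise ConfigurationError(f"covariance for {cls} is not positive semi-definite")
        return arr

    def validate(self) -> None:
        if not self.eaa_list:
            raise ConfigurationError("eaa_list must be non-empty")
        if len(set(self.eaa_list)) != len(self.eaa_list):
            raise ConfigurationError("eaa_list contains duplicates")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.n_per_group < 1 or self.replicates_per_sample < 1 or self.n_diet_samples < 1:
            raise ConfigurationError("sample and replicate counts must be >= 1")
        for organ, p in self.turnover.items():
            if not (0.0 <= float(p) <= 1.0):
                raise ConfigurationError(f"turnover fraction for {organ} outside [0, 1]")
        for grp, f in self.f_microbial.items():
            if not (0.0 <= float(f) <= 1.0):
                raise ConfigurationError(f"f_microbial for {grp} outside [0, 1]")
        if float(self.f_microbial.get("GF", 0.0)) != 0.0:
            raise ConfigurationError("GF animals are germ-free: f_microbial['GF'] must be 0")
        if set(self.endmember_means) != set(self.endmember_cov):
            raise ConfigurationError("endmember_means and endmember_cov list different classes")
        if set(self.endmember_means) != set(self.n_per_endmember_class):
            raise ConfigurationError("endmember class counts do not match the mean table")
        for cls in self.endmember_means:
            _vector(self.endmember_means[cls], self.eaa_list, f"endmember_means[{cls}]")
            self.class_cov(cls)
        self.vec_diet_new(), self.vec_diet_old(), self.vec_microbe()

    # -- serialization ---------------------------------------------------
    _FIELDS = ("eaa_list", "endmember_means", "endmember_cov", "n_per_endmember_class",
               "diet_new", "diet_old", "microbe_source", "turnover", "f_microbial",
               "trophic_offset", "noise_sd", "n_per_group", "replicates_per_sample",
               "n_diet_samples", "seed")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["eaa_list"] = list(self.eaa_list)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        unknown = sorted(set(d) - set(cls._FIELDS))
        if unknown:
            raise ConfigurationError(f"unknown configuration key(s): {', '.join(unknown)}")
        return cls(**dict(d))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, Mapping):
            raise ConfigurationError("configuration file must contain a mapping")
        return cls.from_dict(d)


@dataclass
class SimulatedStudy:
    """A generated study: measurement table plus retained ground truth."""

    measurements: pd.DataFrame
    training: EndmemberTrainingSet
    config: SimulationConfig
    expected: dict  # (group, organ) -> per-EAA expected delta13C before noise


def _rng(config: SimulationConfig, stream: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, _STREAM[stream], *extra])


def expected_tissue(config: SimulationConfig, organ: str, group: str) -> np.ndarray:
    """Expected per-EAA tissue delta13C before measurement noise.

    Implements the single-pool incorporation mixture: the organ's renewed
    fraction ``p`` carries the (1 - f) diet / f microbe mixture plus any
    trophic offset, and the remaining (1 - p) fraction retains the
    pre-switch diet signal.
    """
    if organ not in config.turnover:
        raise ConfigurationError(f"unknown organ {organ!r}; turnover mapping has "
                                 f"{sorted(config.turnover)}")
    p = float(config.turnover[organ])
    f = float(config.f_microbial.get(group, 0.0))
    new_pool = ((1.0 - f) * config.vec_diet_new() + f * config.vec_microbe()
                + config.vec_trophic())
    return p * new_pool + (1.0 - p) * config.vec_diet_old()


def simulate_endmembers(config: SimulationConfig) -> EndmemberTrainingSet:
    """Draw endmember reference profiles from each class's multivariate normal."""
    rows, labels, ids = [], [], []
    for ci, cls in enumerate(sorted(config.endmember_means)):
        mean = _vector(config.endmember_means[cls], config.eaa_list, cls)
        cov = config.class_cov(cls)
        n = int(config.n_per_endmember_class[cls])
        rng = _rng(config, "endmembers", ci)
        draws = rng.multivariate_normal(mean, cov, size=n, method="svd")
        rows.append(draws)
        labels.extend([cls] * n)
        ids.extend([f"{cls}_{i + 1:02d}" for i in range(n)])
    return EndmemberTrainingSet(np.vstack(rows), np.array(labels),
                                tuple(config.eaa_list), tuple(ids))


def _melt_block(values: np.ndarray, sample_ids: list[str], group: str, organ: str,
                eaas: tuple[str, ...], n_reps: int) -> pd.DataFrame:
    """values shape (n_samples, n_eaa, n_reps) -> long measurement rows."""
    n_s, n_a, _ = values.shape
    return pd.DataFrame({
        "sample_id": np.repeat(sample_ids, n_a * n_reps),
        "group": group,
        "organ": organ,
        "analyte": np.tile(np.repeat(eaas, n_reps), n_s),
        "delta13C": values.reshape(-1),
        "replicate": np.tile(np.arange(1, n_reps + 1), n_s * n_a),
    })


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate a complete synthetic study (consumers, diets, endmembers).

    The GF arm is generated with microbial fraction 0, the CVZ arm with the
    configured fraction; every sample receives
    ``replicates_per_sample`` noisy readings per EAA (independent Gaussian
    noise, SD ``noise_sd``).  Identical config + seed reproduces the study
    exactly.
    """
    config.validate()
    eaas = config.eaa_list
    n_a, n_reps = len(eaas), config.replicates_per_sample
    frames, expected = [], {}

    for gi, group in enumerate(("GF", "CVZ")):
        for oi, organ in enumerate(sorted(config.turnover)):
            mu = expected_tissue(config, organ, group)
            expected[(group, organ)] = mu
            rng = _rng(config, "consumers", gi, oi)
            noise = rng.normal(0.0, config.noise_sd,
                               size=(config.n_per_group, n_a, n_reps))
            values = mu[None, :, None] + noise
            ids = [f"{group}_{organ}_{i + 1:02d}" for i in range(config.n_per_group)]
            frames.append(_melt_block(values, ids, group, organ, eaas, n_reps))

    diet_mu = config.vec_diet_new()
    rng = _rng(config, "diet")
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_diet_samples, n_a, n_reps))
    diet_ids = [f"diet_{i + 1:02d}" for i in range(config.n_diet_samples)]
    frames.append(_melt_block(diet_mu[None, :, None] + noise, diet_ids,
                              "DIET", "none", eaas, n_reps))
    expected[("DIET", "none")] = diet_mu

    training = simulate_endmembers(config)
    em = training.to_frame().rename(columns={"class_label": "class"})
    frames.append(pd.DataFrame({
        "sample_id": em["sample_id"],
        "group": "ENDMEMBER",
        "organ": "none",
        "analyte": em["analyte"],
        "delta13C": em["delta13C"],
        "replicate": 1,
    }))

    measurements = validate_measurements(pd.concat(frames, ignore_index=True))
    return SimulatedStudy(measurements=measurements, training=training,
                          config=config, expected=expected)


def write_study(study: SimulatedStudy, out_dir: str | Path,
                float_format: str = "%.4f") -> dict[str, Path]:
    """Write a simulated study as delimited tables plus a truth file.

    Measurements are rounded to ``float_format`` (default 4 decimals,
    an order of magnitude below analytical precision) so the files are
    byte-stable across platforms.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    m = study.measurements
    paths = {
        "consumers": out_dir / "consumers.csv",
        "diet": out_dir / "diet.csv",
        "training": out_dir / "training.csv",
        "truth": out_dir / "truth.yaml",
    }
    write_measurements(m[m["group"].isin(["GF", "CVZ"])], paths["consumers"],
                       float_format=float_format)
    write_measurements(m[m["group"] == "DIET"], paths["diet"], float_format=float_format)
    tr = study.training.to_frame()
    tr["delta13C"] = tr["delta13C"].map(lambda v: float(float_format % v))
    tr.to_csv(paths["training"], index=False, float_format=float_format)
    truth = {
        "config": study.config.to_dict(),
        "expected": {f"{g}:{o}": [round(float(v), 6) for v in mu]
                     for (g, o), mu in study.expected.items()},
    }
    paths["truth"].write_text(yaml.safe_dump(truth, sort_keys=False))
    return paths
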