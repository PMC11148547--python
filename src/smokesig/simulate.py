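"""Synthetic bulk-methylation generator with a full ground-truth ledger.

Emulates the generative structure the downstream analysis assumes: every
bulk sample is a linear mixture of two cell compartments (epithelial and
immune in buccal/cervical swabs, lymphoid and myeloid in blood), smoking
shifts the compartment means of affected CpGs by an archetype-specific
delta-beta, ex-smoker means partially revert toward never-smoker levels,
and the observed values carry beta-distributed measurement noise around
the mixture mean.

Archetype effect patterns:

* ``epithelial_hypoM``        — hypomethylation of the epithelial compartment
  in both buccal and cervical tissue; blood untouched.
* ``immune_hypoM``            — hypomethylation of the immune compartment in
  buccal/cervical and of blood, stronger in myeloid than lymphoid cells.
* ``distal_epithelial_hyperM``  — hypermethylation confined to cervical
  (not directly smoke-exposed) epithelium.
* ``proximal_epithelial_hyperM`` — hypermethylation confined to buccal
  (directly exposed) epithelium.
* ``null``                    — no smoking effect anywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .deconvolution import CellFractions, ReferenceMatrix
from .io_formats import BetaMatrix, SampleSheet, SHEET_COLUMNS

__all__ = [
    "ARCHETYPES",
    "TISSUES",
    "COMPARTMENTS",
    "SimConfig",
    "SimTruth",
    "SimConfigError",
    "build_truth",
    "simulate_dataset",
    "simulate_reference",
]

ARCHETYPES = (
    "epithelial_hypoM",
    "immune_hypoM",
    "distal_epithelial_hyperM",
    "proximal_epithelial_hyperM",
    "null",
)
TISSUES = ("buccal", "cervical", "blood")
COMPARTMENTS: dict[str, tuple[str, str]] = {
    "buccal": ("epithelial", "immune"),
    "cervical": ("epithelial", "immune"),
    "blood": ("myeloid", "lymphoid"),
}
# the compartment whose proportion is the regression covariate f;
# bulk = f * mu(MIXING) + (1 - f) * mu(other)
MIXING_COMPARTMENT = {"buccal": "immune", "cervical": "immune", "blood": "lymphoid"}

SMOKING_GROUPS = ("never", "ex", "current")

_TISSUE_INDEX = {t: i for i, t in enumerate(TISSUES)}
_STAGE_INDEX = {"truth": 0, "samples": 1, "noise": 2, "phenotype": 3}


class SimConfigError(ValueError):
    pass


def _per_archetype(value, name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        unknown = set(value) - set(ARCHETYPES)
        if unknown:
            raise SimConfigError(f"{name}: unknown archetypes {sorted(unknown)}")
        return {a: float(value.get(a, 0.0)) for a in ARCHETYPES}
    return {a: float(value) for a in ARCHETYPES}


@dataclass
class SimConfig:
    """Study-design knobs of the synthetic cohort.

    Defaults encode the reference study conditions used throughout the test
    suite: 500 CpGs (100 per archetype including null), effect size 0.2 on
    the beta scale, beta-noise concentration kappa = 200 (SD ~ 0.03 at
    mid-range), 150 never- and 150 current-smokers per tissue, and
    epithelial-dominant buccal swabs (immune fraction ~ Beta(2,6)),
    mixed cervical samples (~ Beta(3,4)) and balanced blood lymphoid
    fractions (~ Beta(5,5)).
    """

    n_cpgs: int = 500
    archetype_sizes: Mapping[str, int] = field(
        default_factory=lambda: {a: 100 for a in ARCHETYPES}
    )
    effect_size: float | Mapping[str, float] = 0.2
    # immune_hypoM: lymphoid magnitude as a fraction of the myeloid magnitude
    lymphoid_effect_ratio: float = 0.5
    exsmoker_attenuation: float | Mapping[str, float] = 0.7
    dose_slope: float = 0.0
    noise_precision: float | None = 200.0
    fraction_distributions: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "buccal": (2.0, 6.0),
            "cervical": (3.0, 4.0),
            "blood": (5.0, 5.0),
        }
    )
    n_samples: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: {
            t: {"never": 150, "current": 150} for t in TISSUES
        }
    )
    age_range: tuple[float, float] = (18.0, 70.0)
    age_slope: float = 0.0
    pack_year_range: tuple[float, float] = (5.0, 40.0)
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = {a: int(self.archetype_sizes.get(a, 0)) for a in ARCHETYPES}
        unknown = set(self.archetype_sizes) - set(ARCHETYPES)
        if unknown:
            raise SimConfigError(f"unknown archetypes in archetype_sizes: {sorted(unknown)}")
        if any(v < 0 for v in sizes.values()):
            raise SimConfigError("archetype sizes must be non-negative")
        if sum(sizes.values()) != self.n_cpgs:
            raise SimConfigError(
                f"archetype sizes sum to {sum(sizes.values())}, expected n_cpgs={self.n_cpgs}"
            )
        self.archetype_sizes = sizes
        self.effects = _per_archetype(self.effect_size, "effect_size")
        self.effects["null"] = 0.0
        self.attenuations = _per_archetype(self.exsmoker_attenuation, "exsmoker_attenuation")
        for a, att in self.attenuations.items():
            if not 0.0 <= att <= 1.0:
                raise SimConfigError(f"exsmoker_attenuation[{a}]={att} outside [0,1]")
        if not 0.0 <= self.lymphoid_effect_ratio <= 1.0:
            raise SimConfigError("lymphoid_effect_ratio must be in [0,1]")
        if self.noise_precision is not None and self.noise_precision <= 0:
            raise SimConfigError("noise_precision must be positive (or None for noiseless)")
        for t in self.n_samples:
            if t not in TISSUES:
                raise SimConfigError(f"unknown tissue {t!r} in n_samples")
            bad = set(self.n_samples[t]) - set(SMOKING_GROUPS)
            if bad:
                raise SimConfigError(f"unknown smoking types {sorted(bad)} for {t!r}")
        for t in self.fraction_distributions:
            if t not in TISSUES:
                raise SimConfigError(f"unknown tissue {t!r} in fraction_distributions")

    def rng(self, tissue: str, stage: str) -> np.random.Generator:
        """Independent stream per (tissue, stage) off the single global seed.

        Adding samples to one tissue leaves every other tissue's draws
        untouched.
        """
        key = [int(self.seed), _TISSUE_INDEX.get(tissue, 99), _STAGE_INDEX[stage]]
        return np.random.default_rng(key)


@dataclass
class SimTruth:
    """Ground-truth ledger of a synthetic dataset.

    ``mu[(tissue, compartment)]`` holds per-CpG mean beta for each smoking
    group; ``delta[(tissue, compartment)]`` the current-vs-never difference
    (exactly mu(current) - mu(never)); ``archetype`` the per-CpG label.
    """

    mu: dict[tuple[str, str], pd.DataFrame]
    delta: dict[tuple[str, str], pd.Series]
    archetype: pd.Series
    config: SimConfig

    @property
    def cpg_ids(self) -> pd.Index:
        return self.archetype.index

    def delta_matrix(self) -> pd.DataFrame:
        """True delta-beta profiles in the canonical six-column order."""
        from .cell_specific import DELTA_COLUMNS

        cols = {}
        for name in DELTA_COLUMNS:
            compartment, tissue = name.rsplit("_", 1)
            cols[name] = self.delta[(tissue, compartment)]
        return pd.DataFrame(cols, index=self.cpg_ids)

    def to_json(self, path) -> None:
        payload = {
            "archetype": self.archetype.to_dict(),
            "mu": {
                f"{t}/{c}": df.round(6).to_dict(orient="index")
                for (t, c), df in self.mu.items()
            },
            "delta": {
                f"{t}/{c}": s.round(6).to_dict() for (t, c), s in self.delta.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def _archetype_deltas(config: SimConfig, archetype: str) -> dict[tuple[str, str], float]:
    """Per (tissue, compartment) smoking delta for one archetype."""
    e = config.effects[archetype]
    d = {(t, c): 0.0 for t in TISSUES for c in COMPARTMENTS[t]}
    if archetype == "epithelial_hypoM":
        d[("buccal", "epithelial")] = -e
        d[("cervical", "epithelial")] = -e
    elif archetype == "immune_hypoM":
        d[("buccal", "immune")] = -e
        d[("cervical", "immune")] = -e
        d[("blood", "myeloid")] = -e
        d[("blood", "lymphoid")] = -e * config.lymphoid_effect_ratio
    elif archetype == "distal_epithelial_hyperM":
        d[("cervical", "epithelial")] = e
    elif archetype == "proximal_epithelial_hyperM":
        d[("buccal", "epithelial")] = e
    return d


def _bimodal(rng: np.random.Generator, n: int, mode: str) -> np.ndarray:
    """Unit-scale baseline draws: low mode, high mode, or a 50/50 mix."""
    if mode == "low":
        return rng.beta(2.0, 8.0, size=n)
    if mode == "high":
        return rng.beta(8.0, 2.0, size=n)
    low = rng.beta(2.0, 8.0, size=n)
    high = rng.beta(8.0, 2.0, size=n)
    return np.where(rng.random(n) < 0.5, low, high)


def build_truth(config: SimConfig) -> SimTruth:
    """Draw compartment baselines and apply archetype smoking effects.

    Baselines are bimodal over (0.05, 0.95); compartments slated for a
    negative delta draw from the high (methylated) mode and positive deltas
    from the low mode, so the configured effect always has headroom.  A
    config whose effect still pushes a mean outside (0, 1) is rejected.
    """
    rng = config.rng("buccal", "truth")  # single truth stream
    width = len(str(config.n_cpgs))
    cpg_ids = pd.Index(
        [f"cpg{i:0{max(width, 5)}d}" for i in range(1, config.n_cpgs + 1)], name="cpg_id"
    )
    labels = np.concatenate(
        [np.repeat(a, config.archetype_sizes[a]) for a in ARCHETYPES]
    )
    archetype = pd.Series(labels, index=cpg_ids, name="archetype")

    deltas_by_arch = {a: _archetype_deltas(config, a) for a in ARCHETYPES}
    mu: dict[tuple[str, str], pd.DataFrame] = {}
    delta: dict[tuple[str, str], pd.Series] = {}
    max_dose_extra = abs(config.dose_slope) * config.pack_year_range[1]

    for t in TISSUES:
        for c in COMPARTMENTS[t]:
            d_vec = np.array([deltas_by_arch[a][(t, c)] for a in labels])
            modes = np.where(d_vec < 0, "high", np.where(d_vec > 0, "low", "mix"))
            draw = np.empty(config.n_cpgs)
            for m in ("low", "high", "mix"):
                sel = modes == m
                draw[sel] = _bimodal(rng, int(sel.sum()), m)
            # baseline support shrinks per CpG so the configured effect (plus
            # the worst-case dose term) can never leave (0,1)
            lo = np.where(d_vec < 0, 0.015 - d_vec + max_dose_extra, 0.05)
            hi = np.where(d_vec > 0, 0.985 - d_vec - max_dose_extra, 0.95)
            if (lo >= hi).any():
                i = int(np.argmax(lo >= hi))
                raise SimConfigError(
                    f"effect too large to fit inside (0,1): CpG {cpg_ids[i]!r}, "
                    f"tissue {t!r}, compartment {c!r}, delta {d_vec[i]:+.3f} "
                    f"with dose headroom {max_dose_extra:.3f}"
                )
            base = lo + (hi - lo) * draw
            att = np.array([config.attenuations[a] for a in labels])
            never = base
            current = base + d_vec
            ex = base + (1.0 - att) * d_vec
            affected = d_vec != 0
            worst_lo = np.where(affected, current - max_dose_extra, current)
            worst_hi = np.where(affected, current + max_dose_extra, current)
            for grp, vals in (
                ("never", never),
                ("current", worst_lo),
                ("current", worst_hi),
                ("ex", ex),
            ):
                bad = (vals <= 0.005) | (vals >= 0.995)
                if bad.any():
                    i = int(np.argmax(bad))
                    raise SimConfigError(
                        f"smoking effect pushes mean beta outside (0,1): "
                        f"CpG {cpg_ids[i]!r}, tissue {t!r}, compartment {c!r}, "
                        f"group {grp!r}, value {vals[i]:.4f}"
                    )
            mu[(t, c)] = pd.DataFrame(
                {"never": never, "ex": ex, "current": current}, index=cpg_ids
            )
            delta[(t, c)] = pd.Series(d_vec, index=cpg_ids, name=f"{c}_{t}")

    return SimTruth(mu=mu, delta=delta, archetype=archetype, config=config)


def _draw_phenotypes(
    config: SimConfig, tissue: str
) -> pd.DataFrame:
    rng = config.rng(tissue, "phenotype")
    rows = []
    counts = config.n_samples.get(tissue, {})
    for grp in SMOKING_GROUPS:
        n = int(counts.get(grp, 0))
        if n == 0:
            continue
        ages = rng.uniform(*config.age_range, size=n).round(1)
        if grp == "never":
            py = np.zeros(n)
            dur = np.repeat("NA", n)
        else:
            py = rng.uniform(*config.pack_year_range, size=n).round(1)
            dur = rng.choice(["<=1y", "1-5y", ">5y"], size=n)
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{tissue}_{grp}_{i + 1:03d}",
                    "tissue": tissue,
                    "smoking_type": grp,
                    "age": ages[i],
                    "pack_years": py[i],
                    "duration_category": dur[i],
                    "sex": "F",
                }
            )
    return pd.DataFrame(rows, columns=SHEET_COLUMNS)


def expected_bulk(
    truth: SimTruth,
    tissue: str,
    smoking_type: str,
    f: np.ndarray,
    pack_years: np.ndarray | None = None,
    age: np.ndarray | None = None,
) -> np.ndarray:
    """Noise-free bulk mixture means, CpG x sample.

    ``f`` is the mixing-compartment proportion (immune for buccal/cervical,
    lymphoid for blood).  For current smokers a nonzero ``dose_slope`` adds
    ``dose_slope * pack_years`` to the compartment delta of every affected
    CpG before mixing.
    """
    config = truth.config
    mix_c = MIXING_COMPARTMENT[tissue]
    other_c = next(c for c in COMPARTMENTS[tissue] if c != mix_c)
    cols = {}
    for c in (mix_c, other_c):
        mu_grp = truth.mu[(tissue, c)][smoking_type].to_numpy()[:, None]
        if (
            smoking_type == "current"
            and config.dose_slope != 0.0
            and pack_years is not None
        ):
            affected = (truth.delta[(tissue, c)].to_numpy() != 0.0)[:, None]
            mu_grp = mu_grp + affected * config.dose_slope * pack_years[None, :]
        cols[c] = mu_grp
    m = f[None, :] * cols[mix_c] + (1.0 - f[None, :]) * cols[other_c]
    if config.age_slope != 0.0 and age is not None:
        mid = 0.5 * (config.age_range[0] + config.age_range[1])
        m = m + config.age_slope * (age[None, :] - mid)
    return np.clip(m, 1e-6, 1.0 - 1e-6)


def simulate_dataset(
    truth: SimTruth, config: SimConfig | None = None
) -> dict[str, tuple[BetaMatrix, SampleSheet, CellFractions]]:
    """Generate per-tissue bulk beta matrices with sample sheets and true fractions.

    Observed betas are drawn from a beta distribution with the mixture mean
    and concentration ``noise_precision``; ``noise_precision=None`` switches
    noise off and returns the mixture means exactly.  Fully reproducible
    from the config seed.
    """
    config = config or truth.config
    if config.n_cpgs != len(truth.cpg_ids):
        raise SimConfigError("truth ledger is inconsistent with the config")
    out: dict[str, tuple[BetaMatrix, SampleSheet, CellFractions]] = {}
    for tissue in TISSUES:
        pheno = _draw_phenotypes(config, tissue)
        if pheno.empty:
            continue
        rng_s = config.rng(tissue, "samples")
        rng_n = config.rng(tissue, "noise")
        a, b = config.fraction_distributions.get(tissue, (2.0, 2.0))
        f = rng_s.beta(a, b, size=len(pheno))
        blocks = []
        for grp in SMOKING_GROUPS:
            mask = (pheno["smoking_type"] == grp).to_numpy()
            if not mask.any():
                continue
            m = expected_bulk(
                truth,
                tissue,
                grp,
                f[mask],
                pack_years=pheno.loc[mask, "pack_years"].to_numpy(),
                age=pheno.loc[mask, "age"].to_numpy(),
            )
            blocks.append((mask, m))
        m_full = np.empty((config.n_cpgs, len(pheno)))
        for mask, m in blocks:
            m_full[:, mask] = m
        if config.noise_precision is None:
            observed = m_full
        else:
            kappa = float(config.noise_precision)
            observed = rng_n.beta(m_full * kappa, (1.0 - m_full) * kappa)
        beta = BetaMatrix(
            pd.DataFrame(
                observed, index=truth.cpg_ids, columns=pheno["sample_id"].to_numpy()
            )
        )
        mix_c = MIXING_COMPARTMENT[tissue]
        other_c = next(c for c in COMPARTMENTS[tissue] if c != mix_c)
        fractions = CellFractions(
            pd.DataFrame(
                {mix_c: f, other_c: 1.0 - f},
                index=pd.Index(pheno["sample_id"], name="sample_id"),
            )
        )
        out[tissue] = (beta, SampleSheet(pheno), fractions)
    return out


def simulate_reference(
    truth: SimTruth, tissue: str, n_cpgs: int | None = None
) -> ReferenceMatrix:
    """Never-smoker compartment mean profiles as a deconvolution reference.

    With ``n_cpgs`` set, restricts to the CpGs most discriminative between
    the two compartments (largest absolute between-compartment difference,
    ties broken by CpG id).
    """
    c1, c2 = COMPARTMENTS[tissue]
    ref = pd.DataFrame(
        {
            c1: truth.mu[(tissue, c1)]["never"],
            c2: truth.mu[(tissue, c2)]["never"],
        },
        index=truth.cpg_ids,
    )
    if n_cpgs is not None:
        if n_cpgs > len(ref):
            raise SimConfigError(
                f"requested {n_cpgs} discriminative CpGs but only {len(ref)} exist"
            )
        diff = (ref[c1] - ref[c2]).abs()
        order = pd.DataFrame({"diff": -diff, "cpg": ref.index}).sort_values(
            ["diff", "cpg"]
        )
        ref = ref.loc[order.index[:n_cpgs]].sort_index()
    return ReferenceMatrix(ref)
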