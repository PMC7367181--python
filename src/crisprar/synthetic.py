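"""Synthetic flow-cytometry study generator.

Emulates the measurement campaign the pipeline consumes end to end: a
48-construct paired activation/repression library, a nine-variant
single-guide library, a no-sgRNA control, and a fixative-only blank - six
replicates of >= 20,000 events each by default.

Ground truth follows the analytic model: paired constructs are two-state
promoters with modulated switching rates; single-guide variants (and the
experimental observation they mimic) behave constitutively, so their noise
is exactly ``1/mean`` (the ``k_off = 0`` family with a modulated effective
scale).  The no-sgRNA control is the wild-type two-state promoter.

Event intensities are drawn from a gamma distribution matched to the true
mean and CV^2 (the standard steady-state protein-distribution
approximation); an exact-SSA mode exists for fidelity checks.  Replicates
carry a multiplicative lognormal scale jitter and every event a
multiplicative lognormal measurement error, so the pooled squared CV obeys
``(1+cv_rep^2)(1+cv_meas^2)(1+eta^2) - 1``.

A single global seed expands to per-(group, replicate) generators through a
counter scheme: group ``g`` (its index in the deterministic group order),
replicate ``r`` use ``numpy.random.default_rng([seed, g, r])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cytometry import BLANK_ID, CONTROL_ID, write_events_csv
from .errors import ConfigurationError
from .estimation import predict_construct_rates
from .library import (
    CrisprarConstruct,
    SgRNAModule,
    classify_construct,
    default_library,
    default_single_modules,
)
from .telegraph import CrisprParams, PromoterKinetics, apply_crisprar, mean_expression

__all__ = ["SyntheticDesign", "StudyBundle", "ground_truth", "generate_events", "generate_study"]

#: Below this fraction of the control mean a construct is flagged degenerate
#: (effectively silenced; its summary statistics are dominated by noise floors).
DEGENERATE_MEAN_FRACTION = 0.01


@dataclass(frozen=True)
class SyntheticDesign:
    """Study layout and noise structure of one synthetic campaign."""

    library: list[CrisprarConstruct] = field(default_factory=default_library)
    single_modules: list[SgRNAModule] = field(default_factory=default_single_modules)
    params: CrisprParams = field(default_factory=CrisprParams)
    wt: PromoterKinetics = field(
        default_factory=lambda: PromoterKinetics(k_on=1.0, k_off=1.0, tau=1.0, C=200.0)
    )
    n_replicates: int = 6
    n_events: int = 20_000
    measurement_cv: float = 0.05
    replicate_cv: float = 0.05
    blank_mean_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.n_events < 100:
            raise ConfigurationError("n_events must be >= 100")
        if self.measurement_cv < 0 or self.replicate_cv < 0:
            raise ConfigurationError("noise CVs must be >= 0")


def _single_guide_truth(
    module: SgRNAModule, params: CrisprParams, wt: PromoterKinetics
) -> tuple[float, float, float]:
    """(k_on, k_off, mean) for one saturated single guide."""
    if module.regulation_strength is None:
        raise ConfigurationError(f"module {module.key} has no regulation strength")
    if module.role == "repressor":
        p = replace(params, k_r=module.regulation_strength, k_a=0.0)
        kin = apply_crisprar(wt, p, conc_A=0.0, conc_R=1.0, strand_relation="same")
    else:
        p = replace(params, k_r=0.0, k_a=module.regulation_strength)
        kin = apply_crisprar(wt, p, conc_A=1.0, conc_R=0.0, strand_relation="same")
    return kin.k_on, kin.k_off, mean_expression(kin)


def ground_truth(design: SyntheticDesign) -> pd.DataFrame:
    """Deterministic table of analytic (mean, noise) per measured group.

    ``kind`` is one of ``construct`` (two-state), ``single`` (constitutive,
    noise = 1/mean), ``control`` (wild-type two-state).  The blank carries
    no model truth and is not listed.
    """
    wt, params = design.wt, design.params
    control_mean = wt.C * wt.k_on_wt / (wt.k_on_wt + wt.k_off_wt)
    rows = []
    wt_kin = wt.with_rates(wt.k_on_wt, wt.k_off_wt)
    rows.append(
        {
            "construct_id": CONTROL_ID,
            "kind": "control",
            "k_on": wt_kin.k_on,
            "k_off": wt_kin.k_off,
            "true_mean": control_mean,
            "true_noise": 1.0 / control_mean
            + (wt_kin.k_off / wt_kin.k_on) / (wt.tau * (wt_kin.k_on + wt_kin.k_off) + 1.0),
            "degenerate": False,
        }
    )
    for c in design.library:
        kin, mean, noise = predict_construct_rates(c, params, wt)
        rows.append(
            {
                "construct_id": c.construct_id,
                "kind": "construct",
                "k_on": kin.k_on,
                "k_off": kin.k_off,
                "true_mean": mean,
                "true_noise": noise,
                "degenerate": mean < DEGENERATE_MEAN_FRACTION * control_mean,
            }
        )
    for mod in design.single_modules:
        k_on, k_off, mean = _single_guide_truth(mod, params, wt)
        rows.append(
            {
                "construct_id": f"single:{mod.name}",
                "kind": "single",
                "k_on": k_on,
                "k_off": k_off,
                "true_mean": mean,
                "true_noise": 1.0 / mean,  # constitutive family: k_off-free law
                "degenerate": mean < DEGENERATE_MEAN_FRACTION * control_mean,
            }
        )
    return pd.DataFrame(rows)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal factors with mean 1 and the given CV."""
    if cv == 0.0:
        return np.ones(size)
    s2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2), size=size)


def _draw_group(
    rng: np.random.Generator,
    mean: float,
    eta2: float,
    n_events: int,
    measurement_cv: float,
    replicate_factor: float,
) -> np.ndarray:
    loc = mean * replicate_factor
    if eta2 <= 0.0:
        base = np.full(n_events, loc)
    else:
        shape = 1.0 / eta2
        base = rng.gamma(shape=shape, scale=loc / shape, size=n_events)
    return base * _lognormal_factors(rng, measurement_cv, n_events)


def _group_order(design: SyntheticDesign) -> list[tuple[str, str]]:
    """Deterministic (construct_id, kind) order used by the seed counter."""
    order = [(CONTROL_ID, "control")]
    order += [(c.construct_id, "construct") for c in design.library]
    order += [(f"single:{m.name}", "single") for m in design.single_modules]
    order += [(BLANK_ID, "blank")]
    return order


def generate_events(
    design: SyntheticDesign,
    mode: str = "gamma_approx",
    kinds: tuple[str, ...] = ("control", "construct", "single", "blank"),
) -> pd.DataFrame:
    """Event table for the requested group kinds, reproducible from the design seed.

    ``gamma_approx`` draws gamma intensities matched to the true mean and
    CV^2; ``ssa`` delegates to the exact simulator (recommended only with
    small ``n_events``).  Replicate jitter multiplies a whole replicate and
    measurement noise each event, in both modes.
    """
    if mode not in ("gamma_approx", "ssa"):
        raise ConfigurationError(f"unknown generation mode {mode!r}")
    if mode == "ssa" and design.n_events > 100_000:
        import warnings

        warnings.warn("ssa mode with n_events > 1e5 will be slow", stacklevel=2)
    truth = ground_truth(design).set_index("construct_id")
    control_mean = truth.loc[CONTROL_ID, "true_mean"]
    frames = []
    for g, (cid, kind) in enumerate(_group_order(design)):
        if kind not in kinds:
            continue
        for rep in range(1, design.n_replicates + 1):
            rng = np.random.default_rng([design.seed, g, rep])
            jitter = float(_lognormal_factors(rng, design.replicate_cv, 1)[0])
            if kind == "blank":
                base = rng.gamma(
                    shape=2.0,
                    scale=design.blank_mean_fraction * control_mean / 2.0,
                    size=design.n_events,
                )
                x = base * _lognormal_factors(rng, design.measurement_cv, design.n_events)
            elif mode == "gamma_approx":
                x = _draw_group(
                    rng,
                    mean=float(truth.loc[cid, "true_mean"]),
                    eta2=float(truth.loc[cid, "true_noise"]),
                    n_events=design.n_events,
                    measurement_cv=design.measurement_cv,
                    replicate_factor=jitter,
                )
            else:
                from .ssa import ReactionSystem, sample_steady_state

                row = truth.loc[cid]
                if kind == "single":
                    # constitutive family: always-ON promoter at the modulated scale
                    kin = PromoterKinetics(
                        k_on=1.0, k_off=0.0, tau=design.wt.tau, C=float(row["true_mean"])
                    )
                else:
                    kin = replace(
                        design.wt, k_on=float(row["k_on"]), k_off=float(row["k_off"])
                    )
                sys = ReactionSystem.from_kinetics(kin)
                counts = sample_steady_state(
                    sys, n_cells=design.n_events, seed=int(rng.integers(2**31))
                ).protein_counts
                x = (
                    counts
                    * jitter
                    * _lognormal_factors(rng, design.measurement_cv, design.n_events)
                )
            frames.append(
                pd.DataFrame(
                    {"construct_id": cid, "replicate": rep, "intensity": x}
                )
            )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class StudyBundle:
    """Everything one synthetic campaign produces."""

    events: pd.DataFrame
    ground_truth: pd.DataFrame
    manifest: dict

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "events": outdir / "events.csv",
            "ground_truth": outdir / "ground_truth.tsv",
            "manifest": outdir / "manifest.yaml",
        }
        write_events_csv(self.events, paths["events"])
        self.ground_truth.to_csv(
            paths["ground_truth"], sep="\t", index=False, float_format="%.12g"
        )
        with open(paths["manifest"], "w") as fh:
            yaml.safe_dump(self.manifest, fh, sort_keys=True)
        return paths


def generate_study(design: SyntheticDesign | None = None, mode: str = "gamma_approx") -> StudyBundle:
    """One call yields the full pipeline input: paired library, single-guide
    library, control and blank events plus ground truth and a manifest."""
    design = design if design is not None else SyntheticDesign()
    events = generate_events(design, mode=mode)
    truth = ground_truth(design)
    manifest = {
        "seed": int(design.seed),
        "mode": mode,
        "n_replicates": int(design.n_replicates),
        "n_events": int(design.n_events),
        "measurement_cv": float(design.measurement_cv),
        "replicate_cv": float(design.replicate_cv),
        "blank_mean_fraction": float(design.blank_mean_fraction),
        "wild_type": {
            "k_on_wt": design.wt.k_on_wt,
            "k_off_wt": design.wt.k_off_wt,
            "tau": design.wt.tau,
            "C": design.wt.C,
        },
        "crispr_params": {
            "K_ro": design.params.K_ro,
            "K_ao": design.params.K_ao,
            "K_i": design.params.K_i,
            "K_int1": design.params.K_int1,
            "K_int2": design.params.K_int2,
        },
        "regulation_strengths": {
            m.name: m.regulation_strength for m in design.single_modules
        },
        "n_constructs": len(design.library),
        "seed_scheme": "default_rng([seed, group_index, replicate])",
        "labels": {
            c.construct_id: vars(classify_construct(c)) for c in design.library
        },
    }
    return StudyBundle(events=events, ground_truth=truth, manifest=manifest)
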