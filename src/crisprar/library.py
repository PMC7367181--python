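"""Guide-RNA modules, paired activation/repression constructs, and selection rules.

A *module* is one sgRNA (with its target strand and PAM position relative to
the transcription start site) transcribed from one constitutive promoter.
A *construct* pairs one activating and one repressing module on a single
plasmid; the shared sgRNA pool has capacity 1, split between the two guides
in proportion to their promoter strengths.

Three empirical rules classify each construct:

1. does the activating guide target the non-coding or the coding strand
   (drives the expression mean),
2. do the two guides target the same or opposite strands (same-strand
   competition raises noise),
3. are the two guide concentrations equal or unequal (equal concentrations
   lower noise at low expression).

Two three-layer decision trees built from these rules pick construct sets
with the same mean but graded noise, or the same noise but graded mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "SgRNAModule",
    "CrisprarConstruct",
    "RuleLabels",
    "allocate_concentrations",
    "classify_construct",
    "strand_relation",
    "enumerate_library",
    "decision_tree_select",
    "default_promoters",
    "default_modules",
    "default_single_modules",
    "default_library",
]

#: Relative promoter strengths: the strong Anderson promoter is ~5-fold
#: stronger than the medium and ~12-fold stronger than the weak one.
DEFAULT_PROMOTER_STRENGTHS: dict[str, float] = {"pStr": 12.0, "pMed": 2.4, "pWeak": 1.0}

#: PAM windows (bp upstream of the +1 site): guides landing within ~40-60 bp
#: sterically repress; guides further upstream (~60-100 bp) activate.
REPRESSION_WINDOW: tuple[float, float] = (40.0, 60.0)
ACTIVATION_WINDOW: tuple[float, float] = (60.0, 100.0)

#: Maximal fractional regulation strengths (k_r for repressors, k_a for
#: activators) used as the synthetic ground truth of the four guide variants
#: that enter paired constructs.  Values sit in the range typical for
#: dCas9-omega repression (strong) and activation (moderate), and were fixed
#: once so that the default paired library reproduces the study system's
#: qualitative behaviour: construct sets with matched mean but graded noise
#: (and matched noise but graded mean) spanning all decision-tree leaves
#: exist, and mean-matched same-strand constructs are noisier than
#: opposite-strand ones.
DEFAULT_REGULATION_STRENGTHS: dict[str, float] = {
    "A1": 0.80,
    "A2": 0.70,
    "R2": 0.85,
    "R3": 0.75,
}


@dataclass(frozen=True)
class SgRNAModule:
    """One sgRNA expressed from one constitutive promoter.

    ``pam_position`` is the distance of the PAM from the transcription start
    site in bp (positive, upstream).  ``regulation_strength`` is the
    estimated maximal fractional rate reduction (k_r or k_a); it is ``None``
    until estimated from fold-change data.
    """

    name: str
    role: str  # "activator" | "repressor"
    target_strand: str  # "coding" | "non_coding"
    pam_position: int
    promoter: str
    promoter_strength: float
    regulation_strength: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ("activator", "repressor"):
            raise ConfigurationError(f"unknown role {self.role!r}")
        if self.target_strand not in ("coding", "non_coding"):
            raise ConfigurationError(f"unknown strand {self.target_strand!r}")
        if not (self.promoter_strength > 0):
            raise ConfigurationError("promoter_strength must be > 0")
        lo, hi = REPRESSION_WINDOW if self.role == "repressor" else ACTIVATION_WINDOW
        if not (lo <= self.pam_position <= hi):
            raise ConfigurationError(
                f"{self.role} {self.name}: PAM at {self.pam_position} bp is outside "
                f"the {self.role} window [{lo:g}, {hi:g}] bp upstream of +1"
            )
        if self.regulation_strength is not None and not (
            0.0 <= self.regulation_strength <= 1.0
        ):
            raise ConfigurationError("regulation_strength must lie in [0, 1]")

    @property
    def key(self) -> str:
        return f"{self.name}:{self.promoter}"


@dataclass(frozen=True)
class CrisprarConstruct:
    """A paired activating + repressing module sharing one sgRNA pool.

    ``conc_A + conc_R = 1`` exactly (pool capacity constraint).
    ``transcription_order`` records which module is transcribed first on the
    plasmid; it distinguishes construct ids but carries no model term.
    """

    construct_id: str
    act_module: SgRNAModule
    rep_module: SgRNAModule
    conc_A: float
    conc_R: float
    transcription_order: str = "act_first"  # "act_first" | "rep_first"

    def __post_init__(self) -> None:
        if self.act_module.role != "activator":
            raise ConfigurationError("act_module must have role 'activator'")
        if self.rep_module.role != "repressor":
            raise ConfigurationError("rep_module must have role 'repressor'")
        if self.transcription_order not in ("act_first", "rep_first"):
            raise ConfigurationError(
                f"unknown transcription_order {self.transcription_order!r}"
            )
        if not (self.conc_A > 0 and self.conc_R > 0):
            raise ConfigurationError("allocated concentrations must be positive")
        if abs(self.conc_A + self.conc_R - 1.0) > 1e-12:
            raise ConfigurationError("conc_A + conc_R must equal 1")


@dataclass(frozen=True)
class RuleLabels:
    """Deterministic empirical-rule classification of one construct."""

    rule1: str  # "a_noncoding" | "a_coding"
    rule2: str  # "same_strand" | "opposite_strand"
    rule3: str  # "equal_conc" | "unequal_conc"


def allocate_concentrations(strength_A: float, strength_R: float) -> tuple[float, float]:
    """Split the unit sgRNA pool in proportion to promoter strengths.

    Scale-invariant: only the strength ratio matters.
    """
    if strength_A <= 0 or strength_R <= 0:
        raise ConfigurationError("promoter strengths must be positive")
    total = strength_A + strength_R
    return strength_A / total, strength_R / total


def strand_relation(c: CrisprarConstruct) -> str:
    """'same' if both guides target one strand, else 'opposite'."""
    return "same" if c.act_module.target_strand == c.rep_module.target_strand else "opposite"


def classify_construct(c: CrisprarConstruct, equal_tolerance: float = 0.0) -> RuleLabels:
    """Assign the three empirical-rule labels.

    Rule 3 compares the two promoter strengths; with the default zero
    tolerance only identical strengths (in practice, the same promoter)
    count as equal concentration.
    """
    rule1 = "a_noncoding" if c.act_module.target_strand == "non_coding" else "a_coding"
    rule2 = "same_strand" if strand_relation(c) == "same" else "opposite_strand"
    s_a, s_r = c.act_module.promoter_strength, c.rep_module.promoter_strength
    rel = abs(s_a - s_r) / max(s_a, s_r)
    rule3 = "equal_conc" if rel <= equal_tolerance else "unequal_conc"
    return RuleLabels(rule1=rule1, rule2=rule2, rule3=rule3)


def enumerate_library(
    activation_modules: Sequence[SgRNAModule],
    repression_modules: Sequence[SgRNAModule],
    n_order_swaps: int = 12,
) -> list[CrisprarConstruct]:
    """All activator x repressor pairings, plus order-swapped duplicates.

    With the default 6 x 6 module sets this yields 36 unique pairings plus
    12 transcription-order swaps = 48 constructs.  Swaps are added for the
    first ``n_order_swaps`` pairings in enumeration order (activators outer,
    repressors inner), which makes the library deterministic.
    """
    for modules, role in ((activation_modules, "activator"), (repression_modules, "repressor")):
        keys = [m.key for m in modules]
        if len(keys) != len(set(keys)):
            raise ConfigurationError(f"duplicate {role} module names")
    pairs = [(a, r) for a in activation_modules for r in repression_modules]
    if n_order_swaps > len(pairs):
        raise ConfigurationError(
            f"cannot swap {n_order_swaps} of only {len(pairs)} pairings"
        )
    constructs: list[CrisprarConstruct] = []
    for a, r in pairs:
        conc_A, conc_R = allocate_concentrations(a.promoter_strength, r.promoter_strength)
        constructs.append(
            CrisprarConstruct(
                construct_id=f"{a.key}+{r.key}",
                act_module=a,
                rep_module=r,
                conc_A=conc_A,
                conc_R=conc_R,
                transcription_order="act_first",
            )
        )
    for a, r in pairs[:n_order_swaps]:
        conc_A, conc_R = allocate_concentrations(a.promoter_strength, r.promoter_strength)
        constructs.append(
            CrisprarConstruct(
                construct_id=f"{r.key}+{a.key}",
                act_module=a,
                rep_module=r,
                conc_A=conc_A,
                conc_R=conc_R,
                transcription_order="rep_first",
            )
        )
    return constructs


# ---------------------------------------------------------------------------
# decision-tree selection


_SM_LEAF = {  # layer 2 then layer 3; left-most leaf = least noisy
    ("opposite_strand", "equal_conc"): 0,
    ("opposite_strand", "unequal_conc"): 1,
    ("same_strand", "equal_conc"): 2,
    ("same_strand", "unequal_conc"): 3,
}
_SN_LEAF = {  # layer 2 then layer 3; left-most leaf = lowest mean
    ("a_coding", "opposite_strand"): 0,
    ("a_coding", "same_strand"): 1,
    ("a_noncoding", "opposite_strand"): 2,
    ("a_noncoding", "same_strand"): 3,
}


def _leaf_ranks(df: pd.DataFrame, mode: str) -> pd.Series:
    if mode == "same_mean_diff_noise":
        return df.apply(lambda r: _SM_LEAF[(r["rule2"], r["rule3"])], axis=1)
    return df.apply(lambda r: _SN_LEAF[(r["rule1"], r["rule2"])], axis=1)


def decision_tree_select(
    summaries: pd.DataFrame,
    mode: str,
    mean_tolerance: float = 0.05,
    noise_tolerance: float = 0.10,
    expression_threshold: float = 1.0,
    noise_region_quantile: float = 0.5,
) -> pd.DataFrame:
    """Select constructs that decouple expression mean from noise.

    ``summaries`` needs columns ``construct_id``, ``mean``, ``noise``,
    ``rule1``, ``rule2``, ``rule3`` and, for the same-mean mode,
    ``inv_norm_mean`` (1 / control-normalized mean).

    ``same_mean_diff_noise``: layer 1 keeps the low-expression region
    (``inv_norm_mean > expression_threshold``); layers 2 and 3 walk the
    strand-relation then concentration rules.  The result is a set of
    constructs whose means agree within ``mean_tolerance`` (maximum pairwise
    relative difference), one per decision-tree leaf where several leaves
    are represented, sorted by increasing noise.

    ``same_noise_diff_mean``: layer 1 keeps the low-noise region (noise at
    or below the ``noise_region_quantile`` quantile); layers 2 and 3 walk
    the activator-strand then strand-relation rules; noises agree within
    ``noise_tolerance`` and the result is sorted by increasing mean.

    Returns an empty frame (not an error) when no construct qualifies.
    Ties in the sort retain input order.
    """
    if mode not in ("same_mean_diff_noise", "same_noise_diff_mean"):
        raise ConfigurationError(f"unknown selection mode {mode!r}")
    if summaries.empty:
        raise ConfigurationError("summaries must be nonempty")

    df = summaries.reset_index(drop=True).copy()
    df["_input_order"] = np.arange(len(df))

    if mode == "same_mean_diff_noise":
        if "inv_norm_mean" not in df.columns:
            raise ConfigurationError(
                "same-mean selection needs an 'inv_norm_mean' column"
            )
        df = df[df["inv_norm_mean"] > expression_threshold]
        match_col, order_col, tol = "mean", "noise", mean_tolerance
    else:
        cutoff = df["noise"].quantile(noise_region_quantile)
        df = df[df["noise"] <= cutoff]
        match_col, order_col, tol = "noise", "mean", noise_tolerance

    if df.empty:
        return df.drop(columns="_input_order")

    df = df.copy()
    df["_leaf"] = _leaf_ranks(df, mode)
    df = df.sort_values([match_col, "_input_order"], kind="mergesort").reset_index(drop=True)
    values = df[match_col].to_numpy()

    # maximal sliding windows of pairwise-compatible values; score by leaf
    # coverage, then size, then relative spread
    best = None
    j = 0
    for i in range(len(df)):
        j = max(j, i + 1)
        while j < len(df) and values[j] - values[i] <= tol * values[i]:
            j += 1
        window = df.iloc[i:j]
        score = (
            window["_leaf"].nunique(),
            len(window),
            -(values[j - 1] - values[i]) / values[i],
        )
        if best is None or score > best[0]:
            best = (score, i, j)
    _, i, j = best
    window = df.iloc[i:j]

    if window["_leaf"].nunique() >= 2:
        # one representative per leaf: the construct closest to the window
        # median of the matched quantity (stable tie-break on input order)
        center = window[match_col].median()
        picks = []
        for _, leaf_df in window.groupby("_leaf", sort=True):
            leaf_df = leaf_df.assign(_dist=(leaf_df[match_col] - center).abs())
            leaf_df = leaf_df.sort_values(["_dist", "_input_order"], kind="mergesort")
            picks.append(leaf_df.iloc[0])
        out = pd.DataFrame(picks)
    else:
        out = window

    out = out.sort_values([order_col, "_input_order"], kind="mergesort")
    out = out.drop(columns=[c for c in ("_leaf", "_dist", "_input_order") if c in out.columns])
    out = out.reset_index(drop=True)
    out["selection_rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# default library


def default_promoters() -> dict[str, float]:
    return dict(DEFAULT_PROMOTER_STRENGTHS)


def _module(name, role, strand, pam, promoter, strengths, regulation) -> SgRNAModule:
    return SgRNAModule(
        name=name,
        role=role,
        target_strand=strand,
        pam_position=pam,
        promoter=promoter,
        promoter_strength=strengths[promoter],
        regulation_strength=regulation.get(name),
    )


#: (strand, PAM position) catalogue of the guide variants.  A1/R2 target the
#: coding strand, A2/R3 the non-coding strand; A- and R-variant positions
#: fall in the activation and repression windows respectively.
_VARIANTS: dict[str, tuple[str, str, int]] = {
    "R1": ("repressor", "coding", 42),
    "R2": ("repressor", "coding", 50),
    "R3": ("repressor", "non_coding", 55),
    "A1": ("activator", "coding", 62),
    "A2": ("activator", "non_coding", 68),
    "A3": ("activator", "coding", 78),
    "A4": ("activator", "non_coding", 82),
    "A5": ("activator", "coding", 90),
    "A6": ("activator", "non_coding", 98),
}

#: Ground-truth strengths for the full nine-variant single-guide library;
#: activation peaks at the ~80 bp optimum (A3/A4) and falls off beyond it.
DEFAULT_SINGLE_STRENGTHS: dict[str, float] = {
    "R1": 0.90,
    "R2": DEFAULT_REGULATION_STRENGTHS["R2"],
    "R3": DEFAULT_REGULATION_STRENGTHS["R3"],
    "A1": DEFAULT_REGULATION_STRENGTHS["A1"],
    "A2": DEFAULT_REGULATION_STRENGTHS["A2"],
    "A3": 0.92,
    "A4": 0.88,
    "A5": 0.45,
    "A6": 0.25,
}


def default_modules(
    strengths: dict[str, float] | None = None,
    regulation: dict[str, float] | None = None,
) -> tuple[list[SgRNAModule], list[SgRNAModule]]:
    """Six activation and six repression modules: {pStr,pMed,pWeak} x {A1,A2} / {R2,R3}."""
    strengths = strengths or default_promoters()
    regulation = regulation if regulation is not None else dict(DEFAULT_REGULATION_STRENGTHS)
    acts, reps = [], []
    for promoter in ("pStr", "pMed", "pWeak"):
        for name in ("A1", "A2"):
            role, strand, pam = _VARIANTS[name]
            acts.append(_module(name, role, strand, pam, promoter, strengths, regulation))
        for name in ("R2", "R3"):
            role, strand, pam = _VARIANTS[name]
            reps.append(_module(name, role, strand, pam, promoter, strengths, regulation))
    return acts, reps


def default_single_modules(
    regulation: dict[str, float] | None = None,
    promoter: str = "consensus",
    promoter_strength: float = 12.0,
) -> list[SgRNAModule]:
    """The nine-variant single-guide library (R1-R3, A1-A6), one consensus promoter."""
    regulation = regulation if regulation is not None else dict(DEFAULT_SINGLE_STRENGTHS)
    strengths = {promoter: promoter_strength}
    out = []
    for name in ("R1", "R2", "R3", "A1", "A2", "A3", "A4", "A5", "A6"):
        role, strand, pam = _VARIANTS[name]
        out.append(_module(name, role, strand, pam, promoter, strengths, regulation))
    return out


def default_library(
    strengths: dict[str, float] | None = None,
    regulation: dict[str, float] | None = None,
) -> list[CrisprarConstruct]:
    """The default 48-construct paired library (36 unique pairings + 12 swaps)."""
    acts, reps = default_modules(strengths, regulation)
    return enumerate_library(acts, reps, n_order_swaps=12)


# ---------------------------------------------------------------------------
# structured library configuration


def library_from_config(config: dict) -> list[CrisprarConstruct]:
    """Build a construct library from a structured mapping.

    Expected keys: ``promoters`` (list of ``{name, strength}``), ``sgrnas``
    (list of ``{name, role, strand, pam_position, promoter}`` with optional
    ``regulation_strength``), and either ``enumerate: true`` (full pairing,
    optional ``n_order_swaps``) or explicit ``pairs`` (list of
    ``{act, rep}`` module keys ``name:promoter`` with optional ``order``).
    """
    try:
        strengths = {p["name"]: float(p["strength"]) for p in config["promoters"]}
        sgrna_specs = config["sgrnas"]
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"library config needs 'promoters' and 'sgrnas': {exc}")
    modules: dict[str, SgRNAModule] = {}
    for spec in sgrna_specs:
        promoter = spec["promoter"]
        if promoter not in strengths:
            raise ConfigurationError(f"sgRNA {spec['name']}: unknown promoter {promoter!r}")
        mod = SgRNAModule(
            name=spec["name"],
            role=spec["role"],
            target_strand=spec["strand"],
            pam_position=int(spec["pam_position"]),
            promoter=promoter,
            promoter_strength=strengths[promoter],
            regulation_strength=spec.get("regulation_strength"),
        )
        if mod.key in modules:
            raise ConfigurationError(f"duplicate sgRNA module {mod.key}")
        modules[mod.key] = mod
    if config.get("enumerate"):
        acts = [m for m in modules.values() if m.role == "activator"]
        reps = [m for m in modules.values() if m.role == "repressor"]
        return enumerate_library(acts, reps, n_order_swaps=int(config.get("n_order_swaps", 0)))
    constructs = []
    for pair in config.get("pairs", []):
        act, rep = modules[pair["act"]], modules[pair["rep"]]
        conc_A, conc_R = allocate_concentrations(act.promoter_strength, rep.promoter_strength)
        order = pair.get("order", "act_first")
        cid = f"{act.key}+{rep.key}" if order == "act_first" else f"{rep.key}+{act.key}"
        constructs.append(
            CrisprarConstruct(
                construct_id=cid,
                act_module=act,
                rep_module=rep,
                conc_A=conc_A,
                conc_R=conc_R,
                transcription_order=order,
            )
        )
    if not constructs:
        raise ConfigurationError("library config produced no constructs")
    return constructs


def load_library_yaml(path) -> list[CrisprarConstruct]:
    """Read a library definition from a YAML file (see :func:`library_from_config`)."""
    import yaml

    with open(path) as fh:
        return library_from_config(yaml.safe_load(fh))
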