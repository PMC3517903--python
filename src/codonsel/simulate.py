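"""Synthetic codon alignments on duplicated-gene trees.

The generator emulates the data structure the analyses assume: two
paralog clades (plus, optionally, a single outgroup tip), a codon
alignment a few hundred codons long, and omega regimes drawn from each
model family.  Scenario presets carry parameter values typical of
recently duplicated plant gene pairs: strong purifying selection with a
burst of relaxation on the post-duplication branches (the "age" effect),
per-paralog contrasts, a small positively selected site fraction, or a
clade-divergent site class.

Everything is reproducible from (scenario, seed); per-replicate
substreams are spawned deterministically so replicates are independent
and order-insensitive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from . import engine
from .engine import CodonModelSpec, class_structure
from .genetics import STANDARD_CODE
from .inference import CladeSpec, FitOptions, FitResult, fit_model, likelihood_ratio_test
from .phylo import LabeledPhylogeny, partition_branches, read_newick
from .seqdata import CodonAlignment

__all__ = [
    "SimulationScenario",
    "simulate_alignment",
    "scenario_preset",
    "parameter_recovery",
    "lrt_calibration",
    "random_duplication_tree",
    "default_codon_frequencies",
    "PRESET_NAMES",
]


def default_codon_frequencies() -> np.ndarray:
    """A mildly AT-rich product-form frequency vector over sense codons,
    in the range typical of plant nuclear coding sequence."""
    nt = {  # per codon position: T, C, A, G
        0: {"T": 0.26, "C": 0.19, "A": 0.29, "G": 0.26},
        1: {"T": 0.27, "C": 0.22, "A": 0.31, "G": 0.20},
        2: {"T": 0.28, "C": 0.20, "A": 0.27, "G": 0.25},
    }
    pi = np.array(
        [nt[0][c[0]] * nt[1][c[1]] * nt[2][c[2]] for c in STANDARD_CODE.sense_codons]
    )
    return pi / pi.sum()


def random_duplication_tree(
    n_a: int,
    n_b: int,
    rng: np.random.Generator,
    mean_branch: float = 0.06,
    early_length: float = 0.15,
    outgroup_length: float = 0.5,
    with_outgroup: bool = True,
    prefix_a: str = "a",
    prefix_b: str = "b",
) -> tuple[LabeledPhylogeny, CladeSpec]:
    """Random two-clade tree by coalescent-style pairwise joining.

    Within-clade branch lengths are exponential with the given mean
    (substitutions per codon); the two basal branches carry
    ``early_length`` and the outgroup ``outgroup_length``, giving total
    tree lengths of order 1-3 for the default clade sizes.
    """

    def clade(names: list[str]) -> str:
        parts = [f"{n}:{rng.exponential(mean_branch):.6f}" for n in names]
        while len(parts) > 1:
            i, j = sorted(rng.choice(len(parts), size=2, replace=False))
            merged = f"({parts[i]},{parts[j]}):{rng.exponential(mean_branch):.6f}"
            parts = [p for k, p in enumerate(parts) if k not in (i, j)]
            parts.append(merged)
        return parts[0].rsplit(":", 1)[0]  # drop the length above the clade root

    tips_a = [f"{prefix_a}{i+1}" for i in range(n_a)]
    tips_b = [f"{prefix_b}{i+1}" for i in range(n_b)]
    na = clade(tips_a) if n_a > 1 else tips_a[0]
    if n_b == 0:
        # a single gene clade, as used when fitting site models to one
        # paralog with the outgroup excluded
        newick = f"{na};" if n_a > 1 else f"({na}:0.1);"
        return read_newick(newick), CladeSpec(tips_a, [], [], prefix_a, prefix_b)
    nb = clade(tips_b) if n_b > 1 else tips_b[0]
    if with_outgroup:
        newick = f"({na}:{early_length},{nb}:{early_length},og:{outgroup_length});"
        spec = CladeSpec(tips_a, tips_b, ["og"], prefix_a, prefix_b)
    else:
        newick = f"({na}:{early_length},{nb}:{early_length});"
        spec = CladeSpec(tips_a, tips_b, [], prefix_a, prefix_b)
    return read_newick(newick), spec


@dataclass
class SimulationScenario:
    """A fully specified generating process for one synthetic dataset."""

    name: str
    tree: LabeledPhylogeny
    clades: CladeSpec | None
    model: CodonModelSpec
    params: dict
    n_sites: int
    pi: np.ndarray = field(default_factory=default_codon_frequencies)
    seed: int = 0

    def describe(self) -> dict:
        return {
            "name": self.name,
            "family": self.model.family,
            "k": self.model.k,
            "n_sites": self.n_sites,
            "n_tips": self.tree.n_tips,
            "params": {k: v for k, v in self.params.items()},
            "seed": self.seed,
        }


def simulate_alignment(
    scenario: SimulationScenario, seed: int | None = None
) -> tuple[CodonAlignment, np.ndarray, LabeledPhylogeny]:
    """Evolve codons along the scenario tree.

    Root states are drawn from pi, a site class from the class weights,
    and each branch applies the transition matrix of its
    (class, branch-label) omega.  Returns the tip alignment, the true
    per-site class vector, and the tree.
    """
    if scenario.n_sites < 1:
        raise ValueError("scenario must have at least one site")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    tree = scenario.tree
    pi = scenario.pi
    weights, omega_edges = class_structure(scenario.model, scenario.params, tree)
    kappa = scenario.params["kappa"]
    S = scenario.n_sites
    classes = rng.choice(len(weights), size=S, p=weights)

    states = {tree.root: rng.choice(61, size=S, p=pi)}
    cache: dict[float, engine.RateMatrix] = {}
    for v in reversed(tree.postorder):
        if v == tree.root:
            continue
        parent_states = states[tree.parent[v]]
        child = np.empty(S, dtype=np.int16)
        t = float(tree.edge_length[v])
        for c in np.unique(classes):
            om = float(omega_edges[c, v])
            if om not in cache:
                cache[om] = engine.build_generator(kappa, om, pi)
            P = cache[om].probabilities(t)
            P = P / P.sum(axis=1, keepdims=True)
            cum = np.cumsum(P, axis=1)
            mask = classes == c
            u = rng.random(mask.sum())
            child[mask] = (u[:, None] > cum[parent_states[mask]]).sum(axis=1)
        states[v] = child

    sense = STANDARD_CODE.sense_codons
    taxa = scenario.tree.taxa
    codons = np.vstack([states[tree.tip_ids[t]] for t in taxa]).astype(np.int16)
    nuc = {t: "".join(sense[s] for s in codons[i]) for i, t in enumerate(taxa)}
    aln = CodonAlignment(taxa=list(taxa), codons=codons, nuc_seqs=nuc)
    return aln, classes, tree


# ---------------------------------------------------------------------------
# presets

PRESET_NAMES = (
    "null_m0",
    "lax_like_age",
    "pg_like_paralog",
    "pg11c_like_m8",
    "clade_divergent_md",
)


def scenario_preset(name: str, seed: int = 0, **overrides) -> SimulationScenario:
    """Named scenarios spanning the model families.

    Parameter defaults follow the fitted values for recently duplicated
    Medicago gene pairs: an age effect with early omega 0.14 vs late
    0.05 over ~266 codons; a per-paralog contrast 0.25 vs 0.41; a
    positive-selection class at omega 4.45 with weight 0.10 over 243
    codons; and a clade-divergent class at 1.54 / 3.13.  Overrides:
    n_sites, kappa, omega (null_m0), n_a/n_b (clade sizes), or any
    params entry.
    """
    rng = np.random.default_rng(seed)
    kappa = float(overrides.pop("kappa", 2.0))

    def make(n_a, n_b, with_og, n_sites, family, params, k=None, scheme=None):
        n_a = int(overrides.pop("n_a", n_a))
        n_b = int(overrides.pop("n_b", n_b))
        n_sites = int(overrides.pop("n_sites", n_sites))
        tree, clades = random_duplication_tree(
            n_a, n_b, rng, with_outgroup=with_og
        )
        part = None
        if scheme is not None:
            part = partition_branches(
                tree,
                set(clades.clade_a),
                set(clades.clade_b),
                set(clades.outgroup),
                scheme,
            )
        model = CodonModelSpec(family=family, k=k, partition=part)
        params = dict(params)
        params["kappa"] = kappa
        params.update(overrides.pop("params", {}))
        return SimulationScenario(
            name=name, tree=tree, clades=clades, model=model,
            params=params, n_sites=n_sites, seed=seed,
        )

    if name == "null_m0":
        omega = float(overrides.pop("omega", 0.2))
        scen = make(
            4, 4, True, 300, "M0",
            {"omega": {"OG": omega, "all": omega}}, scheme="M0",
        )
    elif name == "lax_like_age":
        scen = make(
            17, 11, True, 266, "MA",
            {"omega": {"OG": 0.05, "early": 0.14, "late": 0.05}}, scheme="MA",
        )
    elif name == "pg_like_paralog":
        scen = make(
            11, 19, True, 243, "MP",
            {"omega": {"OG": 0.06, "cladeA": 0.25, "cladeB": 0.41}}, scheme="MP",
        )
    elif name == "pg11c_like_m8":
        scen = make(
            10, 0, False, 243, "M8",
            {"p": 0.01, "q": 0.05, "p_ad": 0.10, "omega_ad": 4.45},
        )
    elif name == "clade_divergent_md":
        scen = make(
            9, 10, False, 243, "MD",
            {
                "omegas": [0.12],
                "weights": [0.79, 0.21],
                "omega_a": 1.54,
                "omega_b": 3.13,
            },
            k=2, scheme="CLADE",
        )
    else:
        raise ValueError(f"unknown preset {name!r}; valid names: {PRESET_NAMES}")
    if overrides:
        raise ValueError(f"unused overrides: {sorted(overrides)}")
    return scen


def _flatten_params(params: dict) -> dict[str, float]:
    flat: dict[str, float] = {}
    for key, val in params.items():
        if key == "z":
            continue
        if isinstance(val, dict):
            flat.update({f"{key}[{k}]": float(v) for k, v in val.items()})
        elif isinstance(val, (list, tuple, np.ndarray)):
            flat.update({f"{key}[{i}]": float(v) for i, v in enumerate(val)})
        else:
            flat[key] = float(val)
    return flat


# ---------------------------------------------------------------------------
# recovery and calibration harnesses


def _rep_seeds(seed: int, nreps: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(nreps)


@dataclass
class RecoveryReport:
    scenario: SimulationScenario
    table: pd.DataFrame
    estimates: pd.DataFrame
    n_failed: int

    def to_tsv(self) -> str:
        return self.table.to_csv(sep="\t", index=False, float_format="%.5g")


def parameter_recovery(
    scenario: SimulationScenario,
    nreps: int,
    seed: int = 0,
    options: FitOptions | None = None,
) -> RecoveryReport:
    """Simulate -> fit the true family -> tabulate estimate vs truth.

    Fits use the scenario's true equilibrium frequencies (the quantity
    under study is the substitution parameters, not pi).  Failed fits
    are counted, not fatal.
    """
    if nreps < 2:
        raise ValueError("nreps must be >= 2")
    options = options or FitOptions()
    truth = _flatten_params(scenario.params)
    rows = []
    n_failed = 0
    for rep, ss in enumerate(_rep_seeds(seed, nreps)):
        rng = np.random.default_rng(ss)
        sim_seed = int(rng.integers(2**31))
        aln, _, tree = simulate_alignment(scenario, seed=sim_seed)
        opt = replace(options, seed=int(rng.integers(2**31)))
        try:
            fit = fit_model(aln, tree, scenario.model, opt, pi=scenario.pi)
        except Exception:
            n_failed += 1
            continue
        est = _flatten_params(fit.params)
        est["rep"] = rep
        est["logL"] = fit.logL
        rows.append(est)
    est_df = pd.DataFrame(rows)
    recs = []
    for name, true_val in truth.items():
        if name not in est_df.columns:
            continue
        vals = est_df[name].to_numpy()
        recs.append(
            {
                "parameter": name,
                "truth": true_val,
                "mean": vals.mean(),
                "bias": vals.mean() - true_val,
                "rmse": float(np.sqrt(np.mean((vals - true_val) ** 2))),
                "mc_se": vals.std(ddof=1) / math.sqrt(len(vals)),
                "n": len(vals),
            }
        )
    return RecoveryReport(scenario, pd.DataFrame(recs), est_df, n_failed)


@dataclass
class CalibrationReport:
    scenario: SimulationScenario
    null_family: str
    alt_family: str
    alpha: float
    n: int
    n_reject: int
    rejection_rate: float
    ci_low: float
    ci_high: float
    statistics: np.ndarray
    p_values: np.ndarray
    n_failed: int

    def to_tsv(self) -> str:
        df = pd.DataFrame(
            [
                {
                    "test": f"{self.alt_family} vs {self.null_family}",
                    "alpha": self.alpha,
                    "n": self.n,
                    "n_reject": self.n_reject,
                    "rejection_rate": self.rejection_rate,
                    "ci_low": self.ci_low,
                    "ci_high": self.ci_high,
                    "n_failed": self.n_failed,
                }
            ]
        )
        return df.to_csv(sep="\t", index=False, float_format="%.5g")


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    a = (1 - level) / 2
    lo = 0.0 if k == 0 else float(beta_dist.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1 - a, k + 1, n - k))
    return lo, hi


def fit_nested_pair(
    aln: CodonAlignment,
    tree: LabeledPhylogeny,
    null_model: CodonModelSpec,
    alt_model: CodonModelSpec,
    options: FitOptions,
    pi: np.ndarray,
    freeze_alt_branch_lengths: bool = False,
) -> tuple[FitResult, FitResult]:
    """Fit a nested model pair with the alternative warm-started from
    the null solution (and never allowed a worse likelihood)."""
    fit_null = fit_model(aln, tree, null_model, options, pi=pi)
    init: dict = {"kappa": fit_null.params["kappa"], "edge_lengths": fit_null.edge_lengths}
    nf, af = null_model.family, alt_model.family
    if (nf, af) == ("M8A", "M8"):
        init.update(
            p=fit_null.params["p"], q=fit_null.params["q"],
            p_ad=fit_null.params["p_ad"], omega_ad=1.0 + 1e-6,
        )
    elif (nf, af) == ("M3", "MD"):
        om = fit_null.params["omegas"]
        k = alt_model.k
        init.update(
            omegas=om[: k - 1], omega_a=om[k - 1], omega_b=om[k - 1],
            z=fit_null.params["z"],
        )
    elif nf in BRANCH_SET and af in BRANCH_SET:
        base = fit_null.params["omega"]
        from .phylo import SCHEME_LABELS

        om0 = {}
        for lab in SCHEME_LABELS[af]:
            if lab in base:
                om0[lab] = base[lab]
            elif lab == "OG":
                om0[lab] = base.get("OG", 0.2)
            else:
                stem = lab.split(":")[0]
                om0[lab] = base.get(stem, base.get("all", 0.2))
        init["omega"] = om0
    opt = replace(options, init=init)
    if freeze_alt_branch_lengths:
        opt = replace(opt, fix_branch_lengths=fit_null.edge_lengths)
    fit_alt = fit_model(aln, tree, alt_model, opt, pi=pi)
    if fit_alt.logL < fit_null.logL:
        fit_alt.logL = fit_null.logL  # null lies inside the alternative
    return fit_null, fit_alt


BRANCH_SET = set(engine.BRANCH_FAMILIES)


def lrt_calibration(
    scenario: SimulationScenario,
    test_pair: tuple[str, str],
    nreps: int,
    alpha: float = 0.05,
    seed: int = 0,
    options: FitOptions | None = None,
    freeze_alt_branch_lengths: bool | None = None,
) -> CalibrationReport:
    """Empirical rejection rate of a nested LRT over simulated replicates.

    With a scenario generated under the test's null family this measures
    type-I error; under the alternative it measures power.  For the
    M8-vs-M8A pair the alternative's branch lengths are frozen at the
    null fit by default (the statistic is then a lower bound, keeping
    the check on the conservative side at a fraction of the cost).
    """
    options = options or FitOptions()
    nf, af = test_pair
    if freeze_alt_branch_lengths is None:
        freeze_alt_branch_lengths = nf == "M8A"

    def build_model(fam: str) -> CodonModelSpec:
        k = scenario.model.k
        if fam in BRANCH_SET:
            part = partition_branches(
                scenario.tree,
                set(scenario.clades.clade_a),
                set(scenario.clades.clade_b),
                set(scenario.clades.outgroup),
                fam,
            )
            return CodonModelSpec(family=fam, partition=part)
        if fam == "MD":
            part = partition_branches(
                scenario.tree,
                set(scenario.clades.clade_a),
                set(scenario.clades.clade_b),
                set(),
                "CLADE",
            )
            return CodonModelSpec(family=fam, k=k or 2, partition=part)
        if fam == "M3":
            return CodonModelSpec(family=fam, k=k or 2)
        return CodonModelSpec(family=fam)

    null_model = build_model(nf)
    alt_model = build_model(af)
    stats, pvals = [], []
    n_failed = 0
    for ss in _rep_seeds(seed, nreps):
        rng = np.random.default_rng(ss)
        sim_seed = int(rng.integers(2**31))
        aln, _, tree = simulate_alignment(scenario, seed=sim_seed)
        opt = replace(options, seed=int(rng.integers(2**31)))
        try:
            fit_null, fit_alt = fit_nested_pair(
                aln, tree, null_model, alt_model, opt, scenario.pi,
                freeze_alt_branch_lengths=freeze_alt_branch_lengths,
            )
            test = likelihood_ratio_test(fit_null, fit_alt)
        except Exception:
            n_failed += 1
            continue
        stats.append(test.statistic)
        pvals.append(test.p_value)
    stats_arr, pvals_arr = np.array(stats), np.array(pvals)
    n = len(pvals_arr)
    k_rej = int((pvals_arr < alpha).sum())
    lo, hi = _clopper_pearson(k_rej, n)
    return CalibrationReport(
        scenario=scenario,
        null_family=nf,
        alt_family=af,
        alpha=alpha,
        n=n,
        n_reject=k_rej,
        rejection_rate=k_rej / n if n else float("nan"),
        ci_low=lo,
        ci_high=hi,
        statistics=stats_arr,
        p_values=pvals_arr,
        n_failed=n_failed,
    )
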