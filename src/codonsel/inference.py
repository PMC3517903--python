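"""Maximum-likelihood fitting, likelihood-ratio tests, empirical-Bayes
site posteriors, and the three model batteries (branch, site, clade).

Fitting uses bounded quasi-Newton (L-BFGS-B) on log-transformed
parameters, jointly over branch lengths and model parameters, with
optional multi-start.  Nested models are compared by the usual
likelihood-ratio test, 2*(logL_alt - logL_null) against a chi-square
with df equal to the difference in free parameter counts.  Sites in the
positive-selection (or clade-divergent) class are identified by naive
empirical Bayes at the ML estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import chi2

from . import engine, phylo
from .engine import BRANCH_FAMILIES, CodonModelSpec, class_structure
from .phylo import LabeledPhylogeny, partition_branches
from .seqdata import CodonAlignment, CodonFrequencies, estimate_frequencies

__all__ = [
    "FitOptions",
    "FitResult",
    "LRTResult",
    "SitePosteriorTable",
    "CladeSpec",
    "fit_model",
    "likelihood_ratio_test",
    "site_posteriors",
    "run_model_battery",
    "BatteryReport",
]

# optimizer bounds; the 99 upper bound on omega and the beta shapes
# mirrors the conventional codeml-style ceiling
OMEGA_BOUNDS = (1e-4, 99.0)
KAPPA_BOUNDS = (1e-2, 100.0)
SHAPE_BOUNDS = (5e-3, 99.0)
OMEGA_AD_BOUNDS = (1.0, 99.0)
PAD_BOUNDS = (1e-8, 1.0 - 1e-8)
BL_BOUNDS = (1e-6, 25.0)
Z_BOUNDS = (-12.0, 12.0)


@dataclass
class ParamDef:
    name: str
    lo: float
    hi: float
    init: float
    log: bool = True

    def to_internal(self, x: float) -> float:
        x = min(max(x, self.lo), self.hi)
        return math.log(x) if self.log else x

    def from_internal(self, y: float) -> float:
        return math.exp(y) if self.log else y

    @property
    def internal_bounds(self) -> tuple[float, float]:
        if self.log:
            return (math.log(self.lo), math.log(self.hi))
        return (self.lo, self.hi)


def _softmax_weights(z: np.ndarray) -> np.ndarray:
    full = np.concatenate([[0.0], z])
    full = full - full.max()
    w = np.exp(full)
    return w / w.sum()


def _param_defs(model: CodonModelSpec, init: dict | None = None) -> list[ParamDef]:
    init = init or {}
    defs = [ParamDef("kappa", *KAPPA_BOUNDS, init.get("kappa", 2.0))]
    fam = model.family
    if fam in BRANCH_FAMILIES:
        omega0 = init.get("omega", {})
        for lab in phylo.SCHEME_LABELS[fam]:
            defs.append(ParamDef(f"omega:{lab}", *OMEGA_BOUNDS, omega0.get(lab, 0.2)))
    elif fam in ("M8A", "M8"):
        defs.append(ParamDef("p", *SHAPE_BOUNDS, init.get("p", 0.5)))
        defs.append(ParamDef("q", *SHAPE_BOUNDS, init.get("q", 1.5)))
        defs.append(ParamDef("p_ad", *PAD_BOUNDS, init.get("p_ad", 0.1), log=False))
        if fam == "M8":
            defs.append(ParamDef("omega_ad", *OMEGA_AD_BOUNDS, init.get("omega_ad", 2.0)))
    elif fam in ("M3", "MD"):
        k = model.k
        n_shared = k if fam == "M3" else k - 1
        omegas0 = init.get("omegas", np.linspace(0.05, 0.8, n_shared))
        for i in range(n_shared):
            defs.append(ParamDef(f"omega:{i}", *OMEGA_BOUNDS, float(omegas0[i])))
        if fam == "MD":
            defs.append(ParamDef("omega_a", *OMEGA_BOUNDS, init.get("omega_a", 1.0)))
            defs.append(ParamDef("omega_b", *OMEGA_BOUNDS, init.get("omega_b", 1.0)))
        z0 = init.get("z", np.zeros(k - 1))
        for i in range(k - 1):
            defs.append(ParamDef(f"z:{i}", *Z_BOUNDS, float(z0[i]), log=False))
    else:  # pragma: no cover
        raise ValueError(fam)
    return defs


def _unpack(model: CodonModelSpec, defs: list[ParamDef], x: np.ndarray) -> dict:
    vals = {d.name: d.from_internal(xi) for d, xi in zip(defs, x)}
    fam = model.family
    params: dict = {"kappa": vals["kappa"]}
    if fam in BRANCH_FAMILIES:
        params["omega"] = {
            lab: vals[f"omega:{lab}"] for lab in phylo.SCHEME_LABELS[fam]
        }
    elif fam in ("M8A", "M8"):
        params.update(p=vals["p"], q=vals["q"], p_ad=vals["p_ad"])
        if fam == "M8":
            params["omega_ad"] = vals["omega_ad"]
    else:
        k = model.k
        n_shared = k if fam == "M3" else k - 1
        params["omegas"] = [vals[f"omega:{i}"] for i in range(n_shared)]
        if fam == "MD":
            params["omega_a"] = vals["omega_a"]
            params["omega_b"] = vals["omega_b"]
        z = np.array([vals[f"z:{i}"] for i in range(k - 1)])
        params["weights"] = _softmax_weights(z).tolist()
        params["z"] = z.tolist()
    return params


@dataclass
class FitOptions:
    """Optimizer settings for :func:`fit_model`.

    fix_branch_lengths: None (joint optimization), "input" (keep the
    tree's lengths), or an explicit array over edge ids.
    """

    restarts: int = 1
    seed: int = 0
    maxiter: int = 500
    ftol: float = 1e-9
    fix_branch_lengths: object = None
    init: dict | None = None  # structured params (+ "edge_lengths")


@dataclass
class FitResult:
    """ML fit of one codon model: estimates, logL, parameter count and
    convergence diagnostics."""

    model: CodonModelSpec
    params: dict
    edge_lengths: np.ndarray
    logL: float
    np_: int
    converged: bool
    n_iter: int
    n_eval: int
    n_restarts: int
    seed: int
    pi: np.ndarray = field(repr=False, default=None)

    def summary(self) -> dict:
        out = {
            "family": self.model.family,
            "k": self.model.k,
            "logL": self.logL,
            "np": self.np_,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_eval": self.n_eval,
            "seed": self.seed,
        }
        for key, val in self.params.items():
            if key == "omega":
                out.update({f"omega[{k}]": v for k, v in val.items()})
            elif key != "z":
                out[key] = val
        out["tree_length"] = float(
            sum(self.edge_lengths[e] for e in range(len(self.edge_lengths)))
        )
        return out


def fit_model(
    aln: CodonAlignment,
    tree: LabeledPhylogeny,
    model: CodonModelSpec,
    options: FitOptions | None = None,
    pi: CodonFrequencies | np.ndarray | None = None,
) -> FitResult:
    """Jointly maximize the likelihood over branch lengths and model
    parameters by bounded quasi-Newton with optional multi-start.

    Deterministic given (inputs, options.seed).  Equilibrium frequencies
    are estimated from the alignment under the model's scheme unless
    supplied.
    """
    options = options or FitOptions()
    if pi is None:
        pi = estimate_frequencies(aln, model.freq_scheme)
    pi_vec = pi.pi if isinstance(pi, CodonFrequencies) else np.asarray(pi, float)

    init = dict(options.init or {})
    edge_init = np.asarray(
        init.pop("edge_lengths", tree.edge_length), dtype=float
    ).copy()
    defs = _param_defs(model, init)
    edges = tree.edges

    fixed_bl: np.ndarray | None
    if options.fix_branch_lengths is None:
        fixed_bl = None
        bl_defs = [
            ParamDef(f"bl:{e}", *BL_BOUNDS, max(edge_init[e], BL_BOUNDS[0]))
            for e in edges
        ]
    else:
        if isinstance(options.fix_branch_lengths, str):
            if options.fix_branch_lengths != "input":
                raise ValueError("fix_branch_lengths: None, 'input', or an array")
            fixed_bl = edge_init
        else:
            fixed_bl = np.asarray(options.fix_branch_lengths, float)
        bl_defs = []
    all_defs = defs + bl_defs
    bounds = [d.internal_bounds for d in all_defs]
    x0 = np.array([d.to_internal(d.init) for d in all_defs])

    n_eval = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        params = _unpack(model, defs, x[: len(defs)])
        if fixed_bl is None:
            lengths = np.zeros(tree.n_nodes)
            for d, y in zip(bl_defs, x[len(defs):]):
                lengths[int(d.name.split(":")[1])] = math.exp(y)
        else:
            lengths = fixed_bl
        weights, omega_edges = class_structure(model, params, tree)
        try:
            total, _ = engine.tree_log_likelihood(
                aln.codons, aln.taxa, tree, pi_vec, params["kappa"],
                weights, omega_edges, lengths,
            )
        except (ValueError, FloatingPointError):
            return 1e12
        if not np.isfinite(total):
            return 1e12
        return -total

    rng = np.random.default_rng(options.seed)
    best = None
    for r in range(max(1, options.restarts)):
        if r == 0:
            start = x0
        else:
            jitter = rng.normal(0.0, 0.4, size=len(x0))
            start = np.clip(
                x0 + jitter, [b[0] for b in bounds], [b[1] for b in bounds]
            )
        res = minimize(
            objective,
            start,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": options.maxiter, "ftol": options.ftol, "maxcor": 20},
        )
        if best is None or res.fun < best.fun:
            best = res

    params = _unpack(model, defs, best.x[: len(defs)])
    if fixed_bl is None:
        lengths = np.zeros(tree.n_nodes)
        for d, y in zip(bl_defs, best.x[len(defs):]):
            lengths[int(d.name.split(":")[1])] = math.exp(y)
    else:
        lengths = np.asarray(fixed_bl, float)
    return FitResult(
        model=model,
        params=params,
        edge_lengths=lengths,
        logL=-float(best.fun),
        np_=phylo.count_parameters(tree, model.family, model.k),
        converged=bool(best.success),
        n_iter=int(best.nit),
        n_eval=n_eval,
        n_restarts=max(1, options.restarts),
        seed=options.seed,
        pi=pi_vec,
    )


# ---------------------------------------------------------------------------
# likelihood-ratio tests

_NESTED = {
    ("M0", "MP"), ("M0", "MA"), ("M0", "MPA"),
    ("MP", "MPA"), ("MA", "MPA"),
    ("M8A", "M8"), ("M3", "MD"),
}


@dataclass
class LRTResult:
    """Nested-model likelihood-ratio test: 2*dlogL against chi-square."""

    null_family: str
    alt_family: str
    statistic: float
    df: int
    p_value: float

    def stars(self) -> str:
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


def likelihood_ratio_test(null: FitResult, alt: FitResult) -> LRTResult:
    """Compare nested fits: statistic 2*(logL_alt - logL_null) clipped at
    zero, p-value from the chi-square upper tail with df = delta np."""
    pair = (null.model.family, alt.model.family)
    if pair not in _NESTED:
        raise ValueError(f"models {pair} are not a supported nested pair")
    if pair == ("M3", "MD") and null.model.k != alt.model.k:
        raise ValueError("M3(k) vs MD(k) requires equal class counts")
    df = alt.np_ - null.np_
    if df < 1:
        raise ValueError("alternative must have more free parameters")
    stat = max(0.0, 2.0 * (alt.logL - null.logL))
    return LRTResult(
        null_family=null.model.family,
        alt_family=alt.model.family,
        statistic=stat,
        df=df,
        p_value=float(chi2.sf(stat, df)),
    )


def lrt_from_loglik(logl_null: float, logl_alt: float, df: int) -> tuple[float, float]:
    """Desk arithmetic: statistic and p-value from two log-likelihoods."""
    stat = max(0.0, 2.0 * (logl_alt - logl_null))
    return stat, float(chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# site posteriors


@dataclass
class SitePosteriorTable:
    """Per-site class posteriors from naive empirical Bayes, with the
    positive-selection class flagged at 0.50 / 0.95 / 0.99 and an
    optional mapping to ungapped positions of a reference taxon."""

    posteriors: np.ndarray          # (n_sites, C)
    positive_class: int
    ref_taxon: str | None = None
    ref_position: np.ndarray | None = None   # 1-based, -1 where ref gapped
    ref_amino_acid: list[str] | None = None

    @property
    def positive_posterior(self) -> np.ndarray:
        return self.posteriors[:, self.positive_class]

    def flagged(self, threshold: float = 0.95) -> np.ndarray:
        """Alignment site indices (0-based) whose positive-class
        posterior exceeds the threshold."""
        return np.nonzero(self.positive_posterior > threshold)[0]

    def max_posterior_sites(self, tol: float = 1e-9) -> np.ndarray:
        pp = self.positive_posterior
        return np.nonzero(pp >= pp.max() - tol)[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "site": np.arange(1, len(self.posteriors) + 1),
                "p_positive": self.positive_posterior,
            }
        )
        if self.ref_position is not None:
            df["ref_position"] = self.ref_position
            df["ref_aa"] = self.ref_amino_acid
        df["flag"] = [
            "**" if p > 0.99 else "*" if p > 0.95 else "+" if p > 0.5 else ""
            for p in self.positive_posterior
        ]
        return df


def site_posteriors(
    fit: FitResult,
    aln: CodonAlignment,
    tree: LabeledPhylogeny,
    ref_taxon: str | None = None,
) -> SitePosteriorTable:
    """Naive empirical Bayes: P(class c | site) proportional to
    weight_c * L_c(site) at the ML estimates."""
    model = fit.model
    if model.positive_class is not None:
        pos = model.positive_class
    elif model.family == "M8A":
        pos = model.ncat_beta  # the neutral class, for completeness
    elif model.family == "M3":
        pos = int(np.argmax(fit.params["omegas"]))  # least-constrained class
    else:
        raise ValueError(f"{model.family} has no site-class mixture to score")
    weights, omega_edges = class_structure(model, fit.params, tree)
    if len(weights) < 2:
        raise ValueError("site posteriors need a multi-class model")
    _, table = engine.tree_log_likelihood(
        aln.codons, aln.taxa, tree, fit.pi, fit.params["kappa"],
        weights, omega_edges, fit.edge_lengths,
    )
    logw = np.log(np.maximum(weights, 1e-300))
    joint = table + logw[None, :]
    post = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))

    ref_position = None
    ref_aa = None
    if ref_taxon is not None:
        row = aln.row(ref_taxon)
        ref_position = np.full(aln.length, -1, dtype=int)
        ref_aa = []
        pos_counter = 0
        sense = aln.code.sense_codons
        for s in range(aln.length):
            if row[s] >= 0:
                pos_counter += 1
                ref_position[s] = pos_counter
                ref_aa.append(aln.code.codon_table[sense[row[s]]])
            else:
                ref_aa.append("-")
    return SitePosteriorTable(
        posteriors=post,
        positive_class=pos,
        ref_taxon=ref_taxon,
        ref_position=ref_position,
        ref_amino_acid=ref_aa,
    )


# ---------------------------------------------------------------------------
# model batteries


@dataclass
class CladeSpec:
    """The two paralog clades and the outgroup, as tip-name lists."""

    clade_a: list[str]
    clade_b: list[str]
    outgroup: list[str]
    name_a: str = "cladeA"
    name_b: str = "cladeB"

    def validate(self, taxa: list[str]) -> None:
        a, b, og = set(self.clade_a), set(self.clade_b), set(self.outgroup)
        overlap = (a & b) | (a & og) | (b & og)
        if overlap:
            raise ValueError(f"clade lists overlap: {sorted(overlap)}")
        declared = a | b | og
        extra = declared - set(taxa)
        if extra:
            raise ValueError(f"clade lists name unknown taxa: {sorted(extra)}")


@dataclass
class BatteryReport:
    """Fits, tests and tables for one battery run."""

    battery: str
    fits: dict
    lrts: list
    table: pd.DataFrame
    posterior_tables: dict = field(default_factory=dict)

    def to_tsv(self) -> str:
        return self.table.to_csv(sep="\t", index=False, float_format="%.5g")


def _display_labels(scheme: str, spec: CladeSpec) -> dict[str, str]:
    ren = {"cladeA": spec.name_a, "cladeB": spec.name_b}
    out = {}
    for lab in phylo.SCHEME_LABELS[scheme]:
        disp = lab
        for key, name in ren.items():
            disp = disp.replace(key, name)
        out[lab] = disp.replace(":early", "_early").replace(":late", "_late")
    return out


def _branch_battery(
    aln: CodonAlignment,
    tree: LabeledPhylogeny,
    spec: CladeSpec,
    options: FitOptions,
    freq_scheme: str,
) -> BatteryReport:
    a, b, og = set(spec.clade_a), set(spec.clade_b), set(spec.outgroup)
    pi = estimate_frequencies(aln, freq_scheme)
    fits: dict[str, FitResult] = {}

    def warm(fam: str, prev: FitResult) -> FitOptions:
        # inherit branch lengths and the nearest omegas from a simpler fit
        base = prev.params["omega"]
        om0 = {}
        for lab in phylo.SCHEME_LABELS[fam]:
            if lab in base:
                om0[lab] = base[lab]
            elif lab == "OG":
                om0[lab] = base.get("OG", 0.2)
            else:
                stem = lab.split(":")[0]          # MPA labels: clade or age axis
                age = lab.split(":")[-1]
                om0[lab] = base.get(stem, base.get(age, base.get("all", 0.2)))
        opt = FitOptions(**{**options.__dict__})
        opt.init = {
            "kappa": prev.params["kappa"],
            "omega": om0,
            "edge_lengths": prev.edge_lengths,
        }
        return opt

    for fam in BRANCH_FAMILIES:
        part = partition_branches(tree, a, b, og, fam)
        model = CodonModelSpec(family=fam, freq_scheme=freq_scheme, partition=part)
        if fam == "M0":
            fits[fam] = fit_model(aln, tree, model, options, pi=pi)
        elif fam in ("MP", "MA"):
            fits[fam] = fit_model(aln, tree, model, warm(fam, fits["M0"]), pi=pi)
        else:  # MPA: start from whichever one-axis model fits better
            starts = sorted(
                (fits["MA"], fits["MP"]), key=lambda f: f.logL, reverse=True
            )
            cands = [fit_model(aln, tree, model, warm(fam, s), pi=pi) for s in starts]
            fits[fam] = max(cands, key=lambda f: f.logL)
        # a richer nested model can never fit worse than its parent
        parents = {"MP": ["M0"], "MA": ["M0"], "MPA": ["MA", "MP"]}.get(fam, [])
        floor = max((fits[p].logL for p in parents), default=-np.inf)
        if fits[fam].logL < floor:
            fits[fam].logL = floor
    comparisons = [("M0", "MA"), ("M0", "MP"), ("MP", "MPA"), ("MA", "MPA")]
    lrts = [likelihood_ratio_test(fits[n], fits[alt]) for n, alt in comparisons]

    rows = []
    lrt_by_alt = {(t.null_family, t.alt_family): t for t in lrts}
    for fam in BRANCH_FAMILIES:
        fit = fits[fam]
        disp = _display_labels(fam, spec)
        tests = [t for (n, altf), t in lrt_by_alt.items() if altf == fam]
        for i, lab in enumerate(phylo.SCHEME_LABELS[fam]):
            t = tests[i] if i < len(tests) else None
            rows.append(
                {
                    "Model": fam if i == 0 else "",
                    "logL": round(fit.logL, 2) if i == 0 else np.nan,
                    "np": fit.np_ if i == 0 else np.nan,
                    "Branches": disp[lab],
                    "omega": round(fit.params["omega"][lab], 2),
                    "LRT_vs": f"vs. {t.null_family}" if t else "",
                    "LRT": round(t.statistic, 2) if t else np.nan,
                    "p_value": t.p_value if t else np.nan,
                }
            )
    return BatteryReport("branch", fits, lrts, pd.DataFrame(rows))


def _site_battery(
    aln: CodonAlignment,
    tree: LabeledPhylogeny,
    spec: CladeSpec,
    options: FitOptions,
    freq_scheme: str,
    ref_taxon: str | None = None,
) -> BatteryReport:
    fits: dict[str, dict[str, FitResult]] = {}
    lrts = []
    posterior_tables = {}
    rows = []
    genes = [(spec.name_a, spec.clade_a), (spec.name_b, spec.clade_b)]
    for gene, tips in genes:
        sub_aln = aln.subset(list(tips))
        sub_tree = tree.subtree(list(tips))
        pi = estimate_frequencies(sub_aln, freq_scheme)
        m8a = CodonModelSpec(family="M8A", freq_scheme=freq_scheme)
        fit_null = fit_model(sub_aln, sub_tree, m8a, options, pi=pi)
        m8 = CodonModelSpec(family="M8", freq_scheme=freq_scheme)
        opt_alt = FitOptions(**{**options.__dict__})
        opt_alt.init = {
            "kappa": fit_null.params["kappa"],
            "p": fit_null.params["p"],
            "q": fit_null.params["q"],
            "p_ad": fit_null.params["p_ad"],
            "omega_ad": 1.0 + 1e-6,
            "edge_lengths": fit_null.edge_lengths,
        }
        fit_alt = fit_model(sub_aln, sub_tree, m8, opt_alt, pi=pi)
        if fit_alt.logL < fit_null.logL:
            # the null is on the alternative's boundary: never worse
            fit_alt.logL = fit_null.logL
            fit_alt.params.update(
                p=fit_null.params["p"], q=fit_null.params["q"],
                p_ad=fit_null.params["p_ad"], omega_ad=1.0,
                kappa=fit_null.params["kappa"],
            )
            fit_alt.edge_lengths = fit_null.edge_lengths
        test = likelihood_ratio_test(fit_null, fit_alt)
        ref = ref_taxon if ref_taxon in sub_aln.taxa else sub_aln.taxa[0]
        post = site_posteriors(fit_alt, sub_aln, sub_tree, ref_taxon=ref)
        fits[gene] = {"M8A": fit_null, "M8": fit_alt}
        lrts.append((gene, test))
        posterior_tables[gene] = post
        for fam, fit in (("M8A", fit_null), ("M8", fit_alt)):
            p_, q_ = fit.params["p"], fit.params["q"]
            om_ad = 1.0 if fam == "M8A" else fit.params["omega_ad"]
            rows.append(
                {
                    "Gene": gene,
                    "Model": fam,
                    "np": fit.np_,
                    "logL": round(fit.logL, 2),
                    "Parameters": f"p = {p_:.2f} q = {q_:.2f} "
                    f"omega_ad = {om_ad:.2f} p_ad = {fit.params['p_ad']:.2f}",
                    "LRT_vs": "vs. M8A" if fam == "M8" else "",
                    "LRT": round(test.statistic, 2) if fam == "M8" else np.nan,
                    "p_value": test.p_value if fam == "M8" else np.nan,
                    "sites>0.50": len(post.flagged(0.5)) if fam == "M8" else np.nan,
                    "sites>0.95": len(post.flagged(0.95)) if fam == "M8" else np.nan,
                }
            )
    return BatteryReport("site", fits, lrts, pd.DataFrame(rows), posterior_tables)


def _clade_battery(
    aln: CodonAlignment,
    tree: LabeledPhylogeny,
    spec: CladeSpec,
    options: FitOptions,
    freq_scheme: str,
    ks: tuple[int, ...] = (2, 3),
) -> BatteryReport:
    tips = list(spec.clade_a) + list(spec.clade_b)
    sub_aln = aln.subset(tips)
    sub_tree = tree.subtree(tips)
    pi = estimate_frequencies(sub_aln, freq_scheme)
    part = partition_branches(
        sub_tree, set(spec.clade_a), set(spec.clade_b), set(), "CLADE"
    )
    fits: dict = {}
    lrts = []
    rows = []
    posterior_tables = {}
    for k in ks:
        m3 = CodonModelSpec(family="M3", k=k, freq_scheme=freq_scheme)
        fit_null = fit_model(sub_aln, sub_tree, m3, options, pi=pi)
        md = CodonModelSpec(family="MD", k=k, freq_scheme=freq_scheme, partition=part)
        opt_alt = FitOptions(**{**options.__dict__})
        om = fit_null.params["omegas"]
        opt_alt.init = {
            "kappa": fit_null.params["kappa"],
            "omegas": om[: k - 1],
            "omega_a": om[k - 1],
            "omega_b": om[k - 1],
            "z": fit_null.params["z"],
            "edge_lengths": fit_null.edge_lengths,
        }
        fit_alt = fit_model(sub_aln, sub_tree, md, opt_alt, pi=pi)
        if fit_alt.logL < fit_null.logL:
            fit_alt.logL = fit_null.logL
        test = likelihood_ratio_test(fit_null, fit_alt)
        fits[k] = {"M3": fit_null, "MD": fit_alt}
        lrts.append((k, test))
        posterior_tables[k] = site_posteriors(fit_alt, sub_aln, sub_tree)
        rows.append(
            {
                "Model": f"M3({k})", "np": fit_null.np_,
                "logL": round(fit_null.logL, 2),
                "LRT_vs": "", "LRT": np.nan, "p_value": np.nan,
                "prop": "", "clade": "", "omega": "",
            }
        )
        w = fit_alt.params["weights"]
        shared = fit_alt.params["omegas"]
        detail = [
            ("", "", f"{shared[i]:.2f}", f"{w[i]:.2f}") for i in range(k - 1)
        ] + [
            (spec.name_a, f"{fit_alt.params['omega_a']:.2f}", "", f"{w[k-1]:.2f}"),
            (spec.name_b, f"{fit_alt.params['omega_b']:.2f}", "", ""),
        ]
        first = True
        for clade, om_div, om_shared, prop in detail:
            rows.append(
                {
                    "Model": f"MD({k})" if first else "",
                    "np": fit_alt.np_ if first else np.nan,
                    "logL": round(fit_alt.logL, 2) if first else np.nan,
                    "LRT_vs": f"vs. M3({k})" if first else "",
                    "LRT": round(test.statistic, 2) if first else np.nan,
                    "p_value": test.p_value if first else np.nan,
                    "prop": prop,
                    "clade": clade,
                    "omega": om_div or om_shared,
                }
            )
            first = False
    return BatteryReport("clade", fits, lrts, pd.DataFrame(rows), posterior_tables)


def run_model_battery(
    aln: CodonAlignment,
    tree: LabeledPhylogeny,
    clades: CladeSpec,
    battery: str,
    options: FitOptions | None = None,
    freq_scheme: str = "F3x4",
    ref_taxon: str | None = None,
) -> BatteryReport:
    """Run one of the three analysis batteries.

    branch: M0/MP/MA/MPA on the full tree with a separate outgroup
    ratio, plus the four nested tests.  site: M8A vs M8 separately on
    each paralog clade (outgroup excluded), with positive-site
    posteriors.  clade: M3(k) vs MD(k) for k = 2, 3 on the two clades
    without the outgroup.
    """
    options = options or FitOptions()
    clades.validate(aln.taxa)
    if battery == "branch":
        return _branch_battery(aln, tree, clades, options, freq_scheme)
    if battery == "site":
        return _site_battery(aln, tree, clades, options, freq_scheme, ref_taxon)
    if battery == "clade":
        return _clade_battery(aln, tree, clades, options, freq_scheme)
    raise ValueError(f"unknown battery {battery!r} (branch, site, clade)")
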