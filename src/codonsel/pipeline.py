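"""One-command reproduction of the full analysis design.

A run takes an in-frame codon alignment, a tree, and the two paralog
clades plus outgroup, then executes: pseudogene screening, optional
pairwise-identity summary, the branch battery (M0/MP/MA/MPA), the
per-paralog site battery (M8A/M8 with positive-site posteriors), and
the clade battery (M3(k)/MD(k), k = 2, 3), writing each report as a
tab-separated table alongside a structured run record.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .inference import CladeSpec, FitOptions, run_model_battery
from .phylo import read_newick
from .seqdata import pairwise_identity, read_codon_alignment, screen_orfs

__all__ = ["RunConfig", "run_pipeline", "load_config"]

logger = logging.getLogger("codonsel")

DEFAULT_BATTERIES = ("branch", "site", "clade")


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    alignment: str
    tree: str
    clade_a: list[str]
    clade_b: list[str]
    outgroup: list[str]
    output_dir: str = "codonsel_run"
    alignment_format: str = "fasta"
    name_a: str = "cladeA"
    name_b: str = "cladeB"
    batteries: list[str] = field(default_factory=lambda: list(DEFAULT_BATTERIES))
    freq_scheme: str = "F3x4"
    restarts: int = 1
    seed: int = 0
    reference_taxon: str | None = None
    identity_pairs: list[list[str]] = field(default_factory=list)

    def validate(self) -> None:
        for path in (self.alignment, self.tree):
            if not Path(path).exists():
                raise FileNotFoundError(path)
        a, b, og = set(self.clade_a), set(self.clade_b), set(self.outgroup)
        overlap = (a & b) | (a & og) | (b & og)
        if overlap:
            raise ValueError(f"clade lists overlap: {sorted(overlap)}")
        bad = [x for x in self.batteries if x not in DEFAULT_BATTERIES]
        if bad:
            raise ValueError(f"unknown batteries {bad}; choose from {DEFAULT_BATTERIES}")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured batteries; returns a summary dict and
    writes the report bundle to ``config.output_dir``."""
    t_start = time.time()
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    logger.setLevel(logging.INFO)

    try:
        aln = read_codon_alignment(config.alignment, format=config.alignment_format)
        logger.info("alignment: %d taxa, %d codons", aln.n_taxa, aln.length)
        aln, screen = screen_orfs(aln)
        (outdir / "orf_screen.tsv").write_text(screen.to_tsv())
        if screen.excluded:
            logger.info("excluded as pseudogenes: %s", screen.excluded)

        tree = read_newick(Path(config.tree).read_text())
        shared = [t for t in tree.taxa if t in set(aln.taxa)]
        dropped = set(tree.taxa) - set(shared)
        if dropped:
            logger.info("pruning tree tips without kept sequences: %s", sorted(dropped))
            tree = tree.subtree(shared)
        aln = aln.subset([t for t in aln.taxa if t in set(shared)])

        kept = set(aln.taxa)
        clades = CladeSpec(
            [t for t in config.clade_a if t in kept],
            [t for t in config.clade_b if t in kept],
            [t for t in config.outgroup if t in kept],
            config.name_a,
            config.name_b,
        )
        clades.validate(aln.taxa)

        identities = []
        for pair in config.identity_pairs:
            a, b = pair
            for level in ("nucleotide", "amino-acid"):
                identities.append(
                    {"a": a, "b": b, "level": level,
                     "identity_pct": pairwise_identity(aln, a, b, level)}
                )
        if identities:
            import pandas as pd

            pd.DataFrame(identities).to_csv(
                outdir / "identity.tsv", sep="\t", index=False
            )

        options = FitOptions(restarts=config.restarts, seed=config.seed)
        summary: dict = {
            "version": __version__,
            "config": asdict(config),
            "n_taxa": aln.n_taxa,
            "n_codons": aln.length,
            "screen": screen.status,
            "batteries": {},
            "failures": {},
        }
        for battery in config.batteries:
            logger.info("running %s battery", battery)
            try:
                report = run_model_battery(
                    aln, tree, clades, battery,
                    options=options,
                    freq_scheme=config.freq_scheme,
                    ref_taxon=config.reference_taxon,
                )
            except Exception as exc:  # partial bundle with failure flagged
                logger.exception("%s battery failed", battery)
                summary["failures"][battery] = str(exc)
                continue
            (outdir / f"{battery}_models.tsv").write_text(report.to_tsv())
            for key, post in report.posterior_tables.items():
                post.to_dataframe().to_csv(
                    outdir / f"{battery}_sites_{key}.tsv", sep="\t", index=False
                )
            summary["batteries"][battery] = {
                "lrts": [
                    {
                        "label": str(lab) if not hasattr(lab, "statistic") else "",
                        "test": f"{t.alt_family} vs {t.null_family}",
                        "statistic": t.statistic,
                        "df": t.df,
                        "p_value": t.p_value,
                    }
                    for lab, t in _iter_lrts(report)
                ],
                "fits": _fit_summaries(report),
            }
        summary["runtime_s"] = round(time.time() - t_start, 2)
        (outdir / "run_record.json").write_text(
            json.dumps(summary, indent=2, default=_jsonable)
        )
        return summary
    finally:
        logger.removeHandler(fh)
        fh.close()


def _iter_lrts(report):
    for item in report.lrts:
        if isinstance(item, tuple):
            yield item
        else:
            yield "", item


def _fit_summaries(report) -> dict:
    out = {}
    for key, val in report.fits.items():
        if isinstance(val, dict):
            out[str(key)] = {fam: fit.summary() for fam, fit in val.items()}
        else:
            out[str(key)] = val.summary()
    return out


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
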