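"""File formats and run configuration.

Alignments are read from FASTA or relaxed sequential PHYLIP (via Biopython),
upper-cased, with RNA ``U`` mapped to ``T``.  Chains are written as a
tab-separated trace (one row per retained sample) plus a companion newick
file with one rooted tree per line; consensus trees can also be written as a
NEXUS trees block carrying support annotations.  Run configurations are YAML
with unknown keys rejected, and every output directory receives a manifest
sufficient to re-run the job.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from Bio import AlignIO, SeqIO

from .inference import McmcOptions, McmcRun, PriorSpec
from .likelihood import Alignment
from .models import NRParameters, gc_content
from .summaries import ConsensusTree, RootSplitPosterior
from .trees import root_split_of

__all__ = ["read_alignment", "write_fasta", "write_phylip", "RunConfig",
           "load_config", "write_trace", "read_trace", "write_tree_samples",
           "write_root_split_table", "write_consensus_nexus", "write_manifest"]


# ------------------------------------------------------------------ sequences


def _records_to_alignment(records, path) -> Alignment:
    labels, seqs = [], []
    for rec in records:
        labels.append(rec.id)
        seqs.append(str(rec.seq).upper().replace("U", "T"))
    if not labels:
        raise ValueError(f"no sequences found in {path}")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        shortest = min(zip(labels, seqs), key=lambda ls: len(ls[1]))
        raise ValueError(
            f"ragged alignment in {path}: record {shortest[0]!r} has length "
            f"{len(shortest[1])}, others differ")
    return Alignment(labels, seqs)


def read_alignment(path, fmt: str = "fasta") -> Alignment:
    """Read and validate a nucleotide alignment ("fasta" or "phylip")."""
    path = Path(path)
    if fmt == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        return _records_to_alignment(records, path)
    if fmt == "phylip":
        aln = AlignIO.read(str(path), "phylip-relaxed")
        return _records_to_alignment(list(aln), path)
    raise ValueError(f"unknown alignment format {fmt!r}")


def write_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for label, seq in zip(aln.labels, aln.sequences):
            fh.write(f">{label}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_phylip(aln: Alignment, path) -> None:
    """Relaxed sequential PHYLIP (labels of any length, space-separated)."""
    with open(path, "w") as fh:
        fh.write(f" {aln.n_taxa} {aln.n_sites}\n")
        for label, seq in zip(aln.labels, aln.sequences):
            fh.write(f"{label}  {seq}\n")


# --------------------------------------------------------------------- config


class RunConfig:
    """Validated run configuration (model, priors, chain settings, paths)."""

    _KNOWN = {"model", "alignment", "alignment_format", "starting_tree",
              "output_dir", "seed", "n_categories", "priors", "mcmc"}
    _KNOWN_MCMC = {"chain_length", "burn_in", "thin", "moves_per_sweep",
                   "seed", "proposal_scales", "move_weights",
                   "sample_topology", "log_every"}

    def __init__(self, data: dict) -> None:
        unknown = set(data) - self._KNOWN
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        self.model = data.get("model", "NR")
        if self.model not in ("NR", "HB"):
            raise ValueError(f"model must be NR or HB, got {self.model!r}")
        self.alignment = data.get("alignment")
        self.alignment_format = data.get("alignment_format", "fasta")
        self.starting_tree = data.get("starting_tree")
        self.output_dir = data.get("output_dir", "rootward_out")
        self.seed = int(data.get("seed", 0))
        self.n_categories = int(data.get("n_categories", 4))
        prior_kwargs = dict(data.get("priors") or {})
        self.priors = PriorSpec(**prior_kwargs)
        mcmc = dict(data.get("mcmc") or {})
        unknown = set(mcmc) - self._KNOWN_MCMC
        if unknown:
            raise ValueError(f"unknown mcmc keys: {sorted(unknown)}")
        mcmc.setdefault("seed", self.seed)
        self.mcmc = McmcOptions(**mcmc)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "alignment": self.alignment,
            "alignment_format": self.alignment_format,
            "starting_tree": self.starting_tree,
            "output_dir": str(self.output_dir),
            "seed": self.seed,
            "n_categories": self.n_categories,
            "priors": self.priors.to_dict(),
            "mcmc": {
                "chain_length": self.mcmc.chain_length,
                "burn_in": self.mcmc.burn_in,
                "thin": self.mcmc.thin,
                "moves_per_sweep": self.mcmc.moves_per_sweep,
                "seed": self.mcmc.seed,
                "proposal_scales": self.mcmc.proposal_scales,
                "move_weights": self.mcmc.move_weights,
                "sample_topology": self.mcmc.sample_topology,
                "log_every": self.mcmc.log_every,
            },
        }


def load_config(path, overrides: Optional[dict] = None) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(data)


# ---------------------------------------------------------------------- trace

_TRACE_COLUMNS_NR = ["iteration", "log_likelihood", "log_prior",
                     "sigma_R", "sigma_N", "kappa", "alpha", "root_split"]
_TRACE_COLUMNS_HB = ["iteration", "log_likelihood", "log_prior",
                     "s", "alpha", "root_gc", "root_split"]


def write_trace(run: McmcRun, path) -> None:
    """Tab-separated trace: one row per retained sample."""
    rows = []
    for s in run.samples:
        if isinstance(s.params, NRParameters):
            rows.append([s.iteration, s.log_likelihood, s.log_prior,
                         s.params.sigma_r, s.params.sigma_n, s.params.kappa,
                         s.params.alpha, str(root_split_of(s.tree))])
        else:
            rows.append([s.iteration, s.log_likelihood, s.log_prior,
                         s.params.s, s.params.alpha,
                         gc_content(s.params.pi_root),
                         str(root_split_of(s.tree))])
    cols = _TRACE_COLUMNS_NR if run.model == "NR" else _TRACE_COLUMNS_HB
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_trace(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tree_samples(run: McmcRun, path) -> None:
    """Companion newick file: one rooted tree per retained sample."""
    with open(path, "w") as fh:
        for s in run.samples:
            fh.write(s.tree.newick() + "\n")


def write_root_split_table(posterior: RootSplitPosterior, path) -> None:
    rows = posterior.as_rows()
    pd.DataFrame(rows, columns=["root_split", "probability", "cumulative"]
                 ).to_csv(path, sep="\t", index=False)


def write_consensus_nexus(consensus: ConsensusTree, path) -> None:
    """NEXUS trees block with posterior supports as internal node labels."""
    taxa = sorted(consensus.tree.leaf_labels)
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nbegin taxa;\n")
        fh.write(f"  dimensions ntax={len(taxa)};\n  taxlabels\n")
        for t in taxa:
            fh.write(f"    {t}\n")
        fh.write("  ;\nend;\n\nbegin trees;\n")
        fh.write(f"  tree consensus = [&R] {consensus.newick()}\n")
        fh.write("end;\n")


def write_manifest(out_dir, config: RunConfig, extras: Optional[dict] = None) -> None:
    """Machine-readable record sufficient to re-run the job."""
    from . import __version__
    payload = {"rootward_version": __version__, "config": config.to_dict()}
    if extras:
        payload.update(extras)
    Path(out_dir, "manifest.json").write_text(json.dumps(payload, indent=2))
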