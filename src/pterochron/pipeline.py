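"""Demo pipeline: synthetic data through every stage, with a manifest.

The manifest records, per stage, the seed, the artifact paths and their
SHA-256 checksums.  Deterministic stages reproduce byte-identical artifacts
on rerun with the same manifest; seeded stochastic stages reproduce
identical chains.  No stage mutates its inputs; outputs are write-once.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import contamfilter, fossildiv, supermatrix, synthdata
from .clockdating import (
    ClockModelSpec,
    NodeAgePriorSpec,
    annotated_newick,
    build_calibration_set,
    run_mcmc,
    summarize,
)
from .formats import RunConfig, write_alignment, write_newick_dated


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_demo(outdir: Path, seed: int = 42, iters: int = 2000,
             n_taxa: int = 12, n_genes: int = 8) -> dict:
    """Generate synthetic inputs, run filter, matrix, rank, date; manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = []

    def record(name: str, seed_used, artifacts: list[Path]) -> None:
        for a in artifacts:
            if not a.exists():
                raise FileNotFoundError(f"stage {name} did not produce {a}")
        stages.append({
            "name": name,
            "seed": seed_used,
            "artifacts": {str(a): _sha256(a) for a in artifacts},
        })

    # -- simulate ----------------------------------------------------------
    spec = synthdata.SimulationSpec(
        seed=seed, n_extant_taxa=n_taxa, n_genes=n_genes, root_age=120.0,
        clock=ClockModelSpec("CIR"), gene_length_min=120, gene_length_max=200,
        missing_prob=0.1, gamma_shape=None, gamma_categories=1,
    )
    tree = synthdata.gen_chronogram(spec)
    rates = synthdata.gen_branch_rates(tree, spec.clock, seed + 1)
    genes = synthdata.gen_alignments(tree, rates, spec)
    gene_dir = outdir / "genes"
    gene_dir.mkdir(exist_ok=True)
    tree_path = outdir / "chronogram_true.nwk"
    write_newick_dated(tree, tree_path)
    gene_paths = []
    for g in genes:
        p = gene_dir / f"{g.gene_id}.fasta"
        write_alignment(g, p)
        gene_paths.append(p)
    expr = synthdata.gen_contaminated_expression(
        synthdata.ContaminationSpec(seed=seed + 2, n_datasets=4,
                                    n_transcripts=400, library_size=200_000)
    )
    expr_path = outdir / "expression.csv"
    expr.to_csv(expr_path, index=False)
    record("simulate", seed, [tree_path, expr_path] + gene_paths)

    # -- filter ------------------------------------------------------------
    reports = contamfilter.apply_filter(contamfilter.TranscriptTable(expr))
    filt_path = outdir / "filter_report.csv"
    contamfilter.report_to_frame(reports).to_csv(filt_path, index=False)
    record("filter", None, [filt_path])

    # -- matrix ------------------------------------------------------------
    taxa = tree.taxa
    oset = supermatrix.OrthologSet(
        {g.gene_id: g for g in genes}, ingroup=taxa[2:], outgroup=taxa[:2]
    )
    kept = supermatrix.select_single_copy(oset)
    trimmed = [supermatrix.trim_columns(oset.genes[g]) for g in kept]
    sm = supermatrix.concatenate([g for g in trimmed if g.length], taxa)
    sm_path = outdir / "supermatrix.phy"
    supermatrix.write_supermatrix_phylip(sm, sm_path)
    part_path = outdir / "partitions.csv"
    supermatrix.partitions_frame(sm).to_csv(part_path, index=False)
    record("matrix", None, [sm_path, part_path])

    # -- rank --------------------------------------------------------------
    scores = supermatrix.gene_support_scores(genes, n_boot=30, seed=seed + 3)
    top = supermatrix.select_top_genes(scores, k=min(4, len(genes)))
    rank_path = outdir / "gene_scores.csv"
    pd.DataFrame(
        [(s.gene_id, s.support, s.n_taxa, s.gene_id in top) for s in scores],
        columns=["gene_id", "support", "n_taxa", "selected"],
    ).to_csv(rank_path, index=False)
    record("rank", seed + 3, [rank_path])

    # -- date --------------------------------------------------------------
    # calibrate a few deep nodes at 80% of their true age, soft bound 5%
    internal = sorted(
        (n for n in tree.postorder if n >= tree.n_tips and n != tree.root),
        key=lambda n: -tree.ages[n],
    )
    cals = []
    from .clockdating import Calibration

    for label, n in zip("abc", internal[:3]):
        cals.append(Calibration(label, frozenset(tree.clade_tips(n)),
                                0.8 * tree.ages[n]))
    cfg = RunConfig(seed=seed + 4, iterations=iters, burn_in=iters // 4,
                    thinning=5, age_prior="uniform", gamma_categories=1)
    chain = run_mcmc(
        tree, cfg, genes=[genes[i] for i in range(len(genes))],
        calibrations=cals, clock=ClockModelSpec("CIR"),
        age_prior=NodeAgePriorSpec(kind="uniform"),
    )
    chain_path = outdir / "chain.csv"
    chain.samples.to_csv(chain_path, index=False)
    summ = summarize(chain)
    summ_path = outdir / "summary_nodes.csv"
    summ.nodes.to_csv(summ_path, index=False)
    chrono_path = outdir / "chronogram_posterior.nwk"
    with open(chrono_path, "w") as fh:
        fh.write(annotated_newick(summ) + "\n")
    record("date", seed + 4, [chain_path, summ_path, chrono_path])

    # -- fossil ------------------------------------------------------------
    ts = fossildiv.default_timescale()
    occ, _ = synthdata.gen_fossil_record(
        ["Cavolinioidea", "Gymnosomata"], ts, preservation=0.4,
        richness={"Cavolinioidea": 25, "Gymnosomata": 12}, seed=seed + 5,
    )
    occ_path = outdir / "occurrences.csv"
    occ.to_csv(occ_path, index=False)
    curve_path = outdir / "diversity.csv"
    fossildiv.diversity_report(occ, ts).to_csv(curve_path, index=False)
    record("fossil", seed + 5, [occ_path, curve_path])

    manifest = {"seed": seed, "stages": stages}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
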