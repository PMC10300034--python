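"""End-to-end pipeline and command-line interface.

Stages run in fixed order — qc, classify, diversity/structure, clades,
dating — each writing a TSV into the run directory, plus a manifest
(package versions, seed, input checksums, per-stage row counts) that makes
a re-run bit-identical. Every stage can also be invoked standalone through
its CLI subcommand on prior stage outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .refio import (
    EMPTY_MASK,
    ReferenceGenome,
    SampleMetadata,
    default_mask,
    load_mask,
    load_reference,
    read_metadata,
    read_sequences,
)
from .simulate import (
    BackgroundSpec,
    ClockParams,
    HotspotModel,
    SimCladeSpec,
    profiles_from_records,
    simulate_panel,
    write_panel,
)
from .qc import apply_sample_qc, read_qc_table
from .haplogroup import (
    DEFAULT_SCHEME,
    classify_all,
    composition_table,
    load_haplotree,
)
from .diversity import (
    amova,
    frequency_pca,
    haplotype_diversity,
    nucleotide_diversity,
    pairwise_distances,
    pairwise_phist,
)
from .clades import (
    attach_closest_externals,
    find_focal_clades,
    find_identical_clusters,
    select_haplogroups,
    build_network,
)
from .dating import date_clade, date_report, dating_table

log = logging.getLogger("mitogeo")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    sequences: str
    metadata: str
    tree: str
    mask: str | None = None
    qc_table: str | None = None
    reference: str | None = None  # FASTA; None -> synthetic reference
    reference_seed: int = 0
    focal_region: str = "NorthAfrica"
    rate_per_site_per_year: float = 2.355e-8
    genome_length: int = 16569
    n_permutations: int = 999
    n_bootstrap: int = 1000
    min_clade_size: int = 2
    seed: int = 0
    outdir: str = "mitogeo_run"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for key in ("sequences", "metadata", "tree"):
            val = getattr(self, key)
            if not val:
                raise PipelineError(f"config field '{key}' is required")
            if not Path(val).exists():
                raise PipelineError(f"config field '{key}': path '{val}' does not exist")
        for key in ("mask", "qc_table", "reference"):
            val = getattr(self, key)
            if val and not Path(val).exists():
                raise PipelineError(f"config field '{key}': path '{val}' does not exist")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str, n_in: int, n_out: int) -> None:
    log.info("stage=%s rows_in=%d rows_out=%d", name, n_in, n_out)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Re-running with the same config and inputs reproduces byte-identical
    numeric outputs (all randomness flows from ``config.seed``).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    log.addHandler(fh)
    manifest: dict = {
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "inputs": {},
        "stages": {},
    }
    for key in ("sequences", "metadata", "tree", "mask", "qc_table", "reference"):
        val = getattr(config, key)
        if val:
            manifest["inputs"][key] = {"path": str(val), "sha256": _sha256(val)}
    try:
        clock = ClockParams(config.rate_per_site_per_year, config.genome_length)
        reference = (
            load_reference(config.reference)
            if config.reference
            else ReferenceGenome.synthetic(config.genome_length, seed=config.reference_seed)
        )
        mask = load_mask(config.mask) if config.mask else default_mask()
        tree = load_haplotree(config.tree)
        metadata = read_metadata(config.metadata)
        records = read_sequences(config.sequences, reference)
        profiles = profiles_from_records(records, reference)

        # --- qc ---
        if config.qc_table:
            qc_records = read_qc_table(config.qc_table)
            report = apply_sample_qc(qc_records)
            report.to_frame().to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
            retained = set(report.retained_ids)
            profiles = [p for p in profiles if p.sample_id in retained]
            _stage("qc", report.n_input, report.n_retained)
            manifest["stages"]["qc"] = {"in": report.n_input, "out": report.n_retained}
        by_id = {p.sample_id: p for p in profiles}

        # --- classify ---
        calls = classify_all(profiles, tree, mask)
        pd.DataFrame(
            [(c.sample_id, c.haplogroup, c.score, " ".join(c.found) or ".",
              " ".join(c.missing) or ".", " ".join(c.private) or ".") for c in calls],
            columns=["sample_id", "haplogroup", "score", "found", "missing", "private"],
        ).to_csv(outdir / "haplogroup_calls.tsv", sep="\t", index=False)
        _stage("classify", len(profiles), len(calls))
        manifest["stages"]["classify"] = {"in": len(profiles), "out": len(calls)}

        # --- diversity / structure (focal samples grouped by locality) ---
        focal_profiles = [
            p for p in profiles
            if p.sample_id in metadata and metadata[p.sample_id].macro_region == config.focal_region
        ]
        grouping = {p.sample_id: metadata[p.sample_id].locality for p in focal_profiles}
        div_rows = []
        for loc in sorted(set(grouping.values())):
            pop = [p for p in focal_profiles if grouping[p.sample_id] == loc]
            if len(pop) >= 2:
                h, se = haplotype_diversity(pop, mask)
                pi = nucleotide_diversity(pop, reference.length, mask)
                div_rows.append((loc, len(pop), h, se, pi))
        pd.DataFrame(div_rows, columns=["locality", "n", "haplotype_diversity", "se", "pi"]).to_csv(
            outdir / "diversity.tsv", sep="\t", index=False)
        n_groups_ok = len({g for g in grouping.values()}) >= 2 and all(
            sum(1 for v in grouping.values() if v == g) >= 2 for g in set(grouping.values()))
        if len(focal_profiles) >= 4 and n_groups_ok:
            dist = pairwise_distances(focal_profiles, mask)
            res = amova(dist, grouping, config.n_permutations, config.seed)
            res.to_frame().to_csv(outdir / "amova.tsv", sep="\t", index=False)
            phi, pval = pairwise_phist(dist, grouping, config.n_permutations, config.seed)
            phi.to_csv(outdir / "phist.tsv", sep="\t")
            pval.to_csv(outdir / "phist_pvalues.tsv", sep="\t")
        fractions, counts = composition_table(calls, metadata, DEFAULT_SCHEME)
        fractions.to_csv(outdir / "composition.tsv", sep="\t")
        counts.to_csv(outdir / "composition_counts.tsv", sep="\t")
        if fractions.shape[0] >= 2 and fractions.shape[1] >= 2:
            pca = frequency_pca(fractions)
            pca.coordinates.to_csv(outdir / "pca.tsv", sep="\t")
            pd.DataFrame(
                {"component": pca.coordinates.columns,
                 "explained_fraction": pca.explained_variance},
            ).to_csv(outdir / "pca_explained.tsv", sep="\t", index=False)
        _stage("diversity", len(focal_profiles), len(div_rows))
        manifest["stages"]["diversity"] = {"in": len(focal_profiles), "out": len(div_rows)}

        # --- clades ---
        call_map = {c.sample_id: c.haplogroup for c in calls}
        selected = select_haplogroups(call_map, metadata, config.focal_region,
                                      config.min_clade_size)
        all_clades = []
        for hg in selected:
            hg_profiles = [p for p in profiles if call_map[p.sample_id] == hg]
            found = find_focal_clades(hg_profiles, metadata, config.focal_region, mask,
                                      config.min_clade_size, haplogroup=hg)
            has_external = any(
                metadata[p.sample_id].macro_region != config.focal_region
                for p in hg_profiles if p.sample_id in metadata)
            if has_external:
                found = attach_closest_externals(found, hg_profiles, metadata,
                                                 config.focal_region, mask)
            all_clades.extend(found)
        clade_rows = [
            (c.haplogroup, ",".join(sorted(c.member_ids)),
             " ".join(sorted(c.defining_mutations)) or ".", int(c.is_identical_cluster),
             c.closest_external[0] if c.closest_external else ".",
             c.closest_external[1] if c.closest_external else ".",
             c.closest_external[2] if c.closest_external else ".")
            for c in all_clades
        ]
        pd.DataFrame(clade_rows, columns=[
            "haplogroup", "members", "defining_mutations", "identical_cluster",
            "closest_external_id", "closest_external_region", "closest_external_distance",
        ]).to_csv(outdir / "clades.tsv", sep="\t", index=False)
        net = build_network(focal_profiles, mask) if len(focal_profiles) >= 2 else None
        if net is not None:
            pd.DataFrame(
                [(";".join(a) or "ref", ";".join(b) or "ref", w) for a, b, w in net.edges],
                columns=["haplotype_a", "haplotype_b", "steps"],
            ).to_csv(outdir / "network.tsv", sep="\t", index=False)
        _stage("clades", len(selected), len(all_clades))
        manifest["stages"]["clades"] = {"in": len(selected), "out": len(all_clades)}

        # --- dating ---
        results = []
        entries = []
        for c in all_clades:
            internal, ext = date_clade(c, by_id, clock, mask,
                                       config.n_bootstrap, config.seed)
            results.append(internal)
            if ext:
                results.append(ext)
            entries.append((c, internal, ext))
        dating_table(results).to_csv(outdir / "dating.tsv", sep="\t", index=False)
        date_report(entries, metadata).to_csv(outdir / "date_report.tsv", sep="\t", index=False)
        _stage("dating", len(all_clades), len(results))
        manifest["stages"]["dating"] = {"in": len(all_clades), "out": len(results)}
    except Exception as exc:
        log.removeHandler(fh)
        raise PipelineError(f"pipeline failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as out:
        json.dump(manifest, out, indent=2, sort_keys=True)
    log.removeHandler(fh)
    return outdir


def make_figures(outdir: str | Path) -> list[Path]:
    """Cosmetic figures over an existing report bundle (data live in TSVs)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    written: list[Path] = []

    comp_path = outdir / "composition.tsv"
    if comp_path.exists():
        comp = pd.read_csv(comp_path, sep="\t", index_col=0)
        ax = comp.plot.bar(stacked=True, figsize=(7, 4))
        ax.set_ylabel("fraction")
        ax.set_title("Superhaplogroup composition")
        plt.tight_layout()
        p = outdir / "composition.png"
        plt.savefig(p)
        plt.close()
        written.append(p)

    pca_path = outdir / "pca.tsv"
    if pca_path.exists():
        pca = pd.read_csv(pca_path, sep="\t", index_col=0)
        if {"PC1", "PC2"} <= set(pca.columns):
            fig, ax = plt.subplots(figsize=(5, 4))
            ax.scatter(pca["PC1"], pca["PC2"])
            for name, row in pca.iterrows():
                ax.annotate(str(name), (row["PC1"], row["PC2"]))
            ax.set_xlabel("PC1")
            ax.set_ylabel("PC2")
            plt.tight_layout()
            p = outdir / "pca.png"
            plt.savefig(p)
            plt.close()
            written.append(p)

    report_path = outdir / "date_report.tsv"
    if report_path.exists():
        rep = pd.read_csv(report_path, sep="\t")
        if rep.empty:
            log.info("date chart skipped: no clades")
        else:
            fig, ax = plt.subplots(figsize=(7, max(2, 0.4 * len(rep))))
            regions = sorted(set(rep["external_source_region"].astype(str)))
            cmap = plt.get_cmap("tab10")
            colors = {r: cmap(i % 10) for i, r in enumerate(regions)}
            for y, row in rep.iterrows():
                col = colors[str(row["external_source_region"])]
                ax.plot([row["internal_years"], row["external_years"]], [y, y],
                        color=col, lw=1, alpha=0.7)
                ax.scatter([row["internal_years"]], [y], s=20 + 8 * row["n"], color=col)
                if not np.isnan(row["external_years"]):
                    ax.scatter([row["external_years"]], [y], s=25, color=col, marker="s")
            ax.set_yticks(range(len(rep)))
            ax.set_yticklabels(rep["haplogroup"])
            ax.set_xlabel("years before present")
            ax.set_title("Clade coalescent dates (dot) and closest-external dates (square)")
            plt.tight_layout()
            p = outdir / "dates.png"
            plt.savefig(p)
            plt.close()
            written.append(p)
    return written


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
def cli() -> None:
    """Mitogenome phylogeography toolkit."""


@cli.command()
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
@click.option("--seed", type=int, default=None)
@click.option("--outdir", type=click.Path(), default=None)
def run(config_path: str, seed: int | None, outdir: str | None) -> None:
    """Run the full pipeline from a YAML config."""
    try:
        cfg = RunConfig.from_yaml(config_path, seed=seed, outdir=outdir)
        path = run_pipeline(cfg)
    except PipelineError as exc:
        raise SystemExit(str(exc))
    click.echo(f"run complete: {path}")


@cli.command()
@click.option("--qc-table", required=True, type=click.Path(exists=True))
@click.option("--out", type=click.Path(), default="qc_report.tsv")
def qc(qc_table: str, out: str) -> None:
    """Apply the sample-retention rule to a QC table."""
    report = apply_sample_qc(read_qc_table(qc_table))
    report.to_frame().to_csv(out, sep="\t", index=False)
    click.echo(f"retained {report.n_retained} of {report.n_input}")


@cli.command("simulate")
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
@click.option("--seed", type=int, default=0)
@click.option("--outdir", type=click.Path(), default="sim_panel")
def simulate_cmd(config_path: str, seed: int, outdir: str) -> None:
    """Simulate a labeled panel from a YAML clade config."""
    with open(config_path) as fh:
        raw = yaml.safe_load(fh) or {}
    clock = ClockParams(**raw.get("clock", {}))
    hotspots = HotspotModel(
        sites=frozenset(raw.get("hotspots", {}).get("sites", [])),
        rate_multiplier=raw.get("hotspots", {}).get("rate_multiplier", 1.0),
    )
    specs = [SimCladeSpec(**s) for s in raw.get("clades", [])]
    bg = raw.get("background", {})
    background = BackgroundSpec(
        groups=tuple(tuple(g) for g in bg.get("groups", [])),
        divergence_years=bg.get("divergence_years", 20000.0),
    )
    records, metadata, truth = simulate_panel(
        specs, clock, hotspots, seed, background,
        focal_region=raw.get("focal_region", "NorthAfrica"))
    write_panel(outdir, records, metadata, truth)
    click.echo(f"wrote {len(records)} sequences to {outdir}")


@cli.command("classify")
@click.option("--sequences", required=True, type=click.Path(exists=True))
@click.option("--tree", required=True, type=click.Path(exists=True))
@click.option("--mask", type=click.Path(exists=True), default=None)
@click.option("--reference", type=click.Path(exists=True), default=None)
@click.option("--out", type=click.Path(), default="haplogroup_calls.tsv")
def classify_cmd(sequences: str, tree: str, mask: str | None,
                 reference: str | None, out: str) -> None:
    """Classify sequences against a haplogroup tree."""
    ref = load_reference(reference) if reference else ReferenceGenome.synthetic()
    m = load_mask(mask) if mask else default_mask()
    profiles = profiles_from_records(read_sequences(sequences, ref), ref)
    calls = classify_all(profiles, load_haplotree(tree), m)
    pd.DataFrame(
        [(c.sample_id, c.haplogroup, c.score) for c in calls],
        columns=["sample_id", "haplogroup", "score"],
    ).to_csv(out, sep="\t", index=False)
    click.echo(f"classified {len(calls)} samples")


def main() -> None:  # pragma: no cover
    cli(sys.argv[1:])


if __name__ == "__main__":  # pragma: no cover
    main()
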