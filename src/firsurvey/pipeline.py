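"""End-to-end pipeline: configuration, stage orchestration, run manifest.

Stage order mirrors the survey workflow: k-mer spectrum -> SSR scan ->
primer screening -> diversity statistics -> structure inference -> AMOVA.
A single global seed is split deterministically into per-stage sub-seeds,
so a rerun with the same config reproduces every stochastic stage
bit-for-bit; the manifest records every parameter that affects a numeric
output.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from . import __version__, amova as amova_mod, diversity, io, kmer, ssr, structure, trees


@dataclass
class SpectrumParams:
    k: int = 17
    error_depth_cutoff: int = 3
    prior_depth: float | None = None
    repeat_multiplier: float = 2.0


@dataclass
class SsrParams:
    min_repeats: dict = field(default_factory=lambda: dict(ssr.DEFAULT_MIN_REPEATS))
    design_primers: bool = True
    max_primer_loci: int = 20


@dataclass
class DiversityParams:
    he_correction: str = "unbiased"
    bootstrap_reps: int = 100
    build_tree: bool = True


@dataclass
class StructureParams:
    k_min: int = 1
    k_max: int = 5
    replicates: int = 3
    burn_in: int = 500
    iterations: int = 2_500
    alpha: float = 1.0
    q_threshold: float = 0.6


@dataclass
class AmovaParams:
    permutations: int = 999


@dataclass
class PipelineConfig:
    """All pipeline inputs and per-stage parameter blocks.

    ``fasta``, ``genotypes`` (GenAlEx CSV) are input paths; either may be
    omitted to skip the stages needing it.  Unknown keys are rejected.
    """

    out_dir: str = "results"
    seed: int = 0
    fasta: str | None = None
    histogram: str | None = None
    genotypes: str | None = None
    spectrum: SpectrumParams = field(default_factory=SpectrumParams)
    ssr: SsrParams = field(default_factory=SsrParams)
    diversity: DiversityParams = field(default_factory=DiversityParams)
    structure: StructureParams = field(default_factory=StructureParams)
    amova: AmovaParams = field(default_factory=AmovaParams)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        blocks = {
            "spectrum": SpectrumParams,
            "ssr": SsrParams,
            "diversity": DiversityParams,
            "structure": StructureParams,
            "amova": AmovaParams,
        }
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for key, value in raw.items():
            if key in blocks:
                sub_known = {f.name for f in fields(blocks[key])}
                bad = set(value) - sub_known
                if bad:
                    raise ValueError(f"unknown keys in {key!r}: {sorted(bad)}")
                if key == "ssr" and "min_repeats" in value:
                    value = dict(value)
                    value["min_repeats"] = {
                        int(u): int(r) for u, r in value["min_repeats"].items()
                    }
                kwargs[key] = blocks[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _write_tsv(path: Path, header, rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    f"{v:.4f}" if isinstance(v, float) else str(v) for v in row
                )
                + "\n"
            )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; returns {stage: output paths / values}."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for path in (config.fasta, config.histogram, config.genotypes):
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"input not found: {path}")
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("spectrum", "ssr", "diversity", "structure", "amova"), ss.spawn(5)
        )
    }
    report: dict = {}
    manifest = {
        "package": "firsurvey",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "config": asdict(config),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
    }
    sequences = None
    if config.fasta:
        sequences = _run_stage("read_fasta", lambda: io.read_fasta(config.fasta))

    if config.histogram or sequences:
        def spectrum_stage():
            sp = config.spectrum
            if config.histogram:
                hist = io.read_histogram(config.histogram, k=sp.k)
                cutoff = sp.error_depth_cutoff
            else:
                # assembled sequences carry no sequencing-error spike:
                # depth-1 k-mers are genuine single-copy sequence
                hist = kmer.count_kmers([s for _, s in sequences], k=sp.k)
                cutoff = 1
            peaks, main = kmer.find_peaks(
                hist, error_depth_cutoff=cutoff, prior_depth=sp.prior_depth
            )
            cutoff = max(cutoff, kmer.default_error_cutoff(main)) if config.histogram else cutoff
            size = kmer.estimate_genome_size(hist, main, cutoff)
            het = kmer.estimate_heterozygous_signal(hist, main, cutoff)
            rep = kmer.estimate_repeat_fraction(hist, main, sp.repeat_multiplier, cutoff)
            rows = [
                ("main_peak_depth", float(main)),
                ("genome_size_bp", float(size)),
                ("heterozygous_signal", het),
                ("repeat_fraction", rep),
            ]
            if sequences:
                rows.append(("gc_content", kmer.gc_content([s for _, s in sequences])))
            _write_tsv(out / "spectrum.tsv", ("quantity", "value"), rows)
            return {"genome_size_bp": size, "main_peak_depth": main, "path": str(out / "spectrum.tsv")}

        report["spectrum"] = _run_stage("spectrum", spectrum_stage)
        manifest["stages"].append("spectrum")

    if sequences:
        def ssr_stage():
            loci = ssr.find_ssrs_many(sequences, min_repeats=config.ssr.min_repeats)
            non_n = sum(len(s) - s.count("N") for _, s in sequences)
            summary = ssr.summarize_ssrs(loci, non_n) if loci else None
            _write_tsv(
                out / "ssr_loci.tsv",
                ("sequence_id", "start", "end", "motif", "class", "repeats"),
                [
                    (l.sequence_id, l.start + 1, l.end, l.motif, l.canonical_class, l.repeat_count)
                    for l in loci
                ],
            )
            if summary:
                _write_tsv(
                    out / "ssr_summary.tsv",
                    ("unit_size", "count", "proportion"),
                    [
                        (u, summary.by_unit_size[u], summary.unit_size_proportions()[u])
                        for u in sorted(summary.by_unit_size)
                    ],
                )
            primer_rows = []
            if config.ssr.design_primers:
                seq_by_id = dict(sequences)
                for locus in loci[: config.ssr.max_primer_loci]:
                    pairs = ssr.design_primer_sites(seq_by_id[locus.sequence_id], locus)
                    if pairs:
                        p = pairs[0]
                        primer_rows.append(
                            (
                                locus.sequence_id, locus.start + 1, locus.motif,
                                p.left_start + 1, p.left_end, p.right_start + 1,
                                p.right_end, p.product_size, p.left_tm, p.right_tm,
                            )
                        )
                _write_tsv(
                    out / "ssr_primers.tsv",
                    (
                        "sequence_id", "locus_start", "motif", "left_start", "left_end",
                        "right_start", "right_end", "product", "left_tm", "right_tm",
                    ),
                    primer_rows,
                )
            return {"n_loci": len(loci), "n_primer_loci": len(primer_rows)}

        report["ssr"] = _run_stage("ssr", ssr_stage)
        manifest["stages"].append("ssr")

    G = None
    if config.genotypes:
        G = _run_stage("read_genotypes", lambda: io.read_genotypes(config.genotypes))
    if G is not None:
        def diversity_stage():
            stats = diversity.all_locus_stats(G, config.diversity.he_correction)
            _write_tsv(
                out / "diversity.tsv",
                ("locus", "n", "na", "ne", "ho", "he", "pic", "shannon_i"),
                [(s.locus, s.n, s.na, s.ne, s.ho, s.he, s.pic, s.shannon_i) for s in stats],
            )
            result = {"n_loci": len(stats)}
            if config.diversity.build_tree and G.n_individuals >= 3:
                tree, supports = trees.bootstrap_tree(
                    G, n_reps=config.diversity.bootstrap_reps, seed=stage_seeds["diversity"]
                )
                (out / "nj_tree.nwk").write_text(tree.newick(support=supports) + "\n")
                result["tree"] = str(out / "nj_tree.nwk")
            return result

        report["diversity"] = _run_stage("diversity", diversity_stage)
        manifest["stages"].append("diversity")

        def structure_stage():
            sp = config.structure
            ks = range(sp.k_min, sp.k_max + 1)
            lk_by_k, results = structure.run_k_grid(
                G, ks, n_replicates=sp.replicates, burn_in=sp.burn_in,
                iterations=sp.iterations, seed=stage_seeds["structure"], alpha=sp.alpha,
            )
            rows = []
            best = None
            if len(list(ks)) >= 3 and sp.replicates >= 2:
                ev = structure.evanno_delta_k(lk_by_k)
                best = structure.best_k(ev)
                rows = [
                    (r.k, r.mean_lk, r.sd_lk, "" if r.delta_k is None else r.delta_k)
                    for r in ev
                ]
                _write_tsv(out / "evanno.tsv", ("k", "mean_lk", "sd_lk", "delta_k"), rows)
            k_use = best or max(lk_by_k, key=lambda k: np.mean(lk_by_k[k]))
            consensus = structure.align_replicates([r.q for r in results[k_use]])
            labels = structure.assign_groups(consensus, sp.q_threshold)
            _write_tsv(
                out / "structure_q.tsv",
                ("individual",) + tuple(f"q{j + 1}" for j in range(k_use)) + ("group",),
                [
                    (ind,) + tuple(float(consensus[i, j]) for j in range(k_use)) + (labels[i],)
                    for i, ind in enumerate(G.individuals)
                ],
            )
            return {"best_k": best, "k_used": k_use, "labels": labels}

        report["structure"] = _run_stage("structure", structure_stage)
        manifest["stages"].append("structure")

        def amova_stage():
            labels = report["structure"]["labels"]
            usable = [str(l) for l in labels]
            keep = [i for i, l in enumerate(usable) if l != "mixed"]
            by_group: dict[str, int] = {}
            for i in keep:
                by_group[usable[i]] = by_group.get(usable[i], 0) + 1
            eligible = {g for g, c in by_group.items() if c >= 2}
            keep = [i for i in keep if usable[i] in eligible]
            if len(eligible) < 2:
                return {"skipped": "fewer than 2 assignable groups"}
            from .containers import GenotypeMatrix

            sub = GenotypeMatrix(
                [G.individuals[i] for i in keep], G.loci, G.calls[keep],
            )
            labs = [usable[i] for i in keep]
            table = amova_mod.amova(
                sub, labs, n_permutations=config.amova.permutations,
                seed=stage_seeds["amova"],
            )
            _write_tsv(
                out / "amova.tsv",
                ("source", "df", "ss", "variance", "percent", "phi", "p"),
                [
                    (
                        r.source, r.df, r.ss, r.variance, r.percent,
                        "" if r.phi is None else r.phi,
                        "" if r.p_value is None else r.p_value,
                    )
                    for r in table.rows
                ],
            )
            names, fst, pvals = amova_mod.pairwise_fst(
                sub, labs, n_permutations=config.amova.permutations,
                seed=stage_seeds["amova"] + 1,
            )
            _write_tsv(
                out / "pairwise_fst.tsv",
                ("group_a", "group_b", "fst", "p"),
                [
                    (names[a], names[b], float(fst[a, b]), float(pvals[a, b]))
                    for a in range(len(names))
                    for b in range(a + 1, len(names))
                ],
            )
            nm = amova_mod.nm_from_fst(table.phi_st) if table.phi_st > 0 else float("inf")
            return {"phi_st": table.phi_st, "nm": nm}

        report["amova"] = _run_stage("amova", amova_stage)
        manifest["stages"].append("amova")

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    report["manifest"] = str(out / "manifest.json")
    return report


def _run_stage(name: str, fn):
    try:
        return fn()
    except Exception as exc:  # noqa: BLE001 - stage isolation by design
        raise StageError(name, exc) from exc
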