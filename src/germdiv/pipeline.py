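"""One-shot pipeline: run the marker, barcode and trait analyses from a
YAML config and write every artefact plus a run manifest.

Outputs are plain text (TSV tables, PHYLIP matrices, Newick trees) and a
``manifest.json`` echoing the config, package version, seed and any
warnings.  Stage timings go to the log stream only, so reruns with the
same config and seed produce byte-identical files.  If any stage fails,
files already written by this run are removed and the error is re-raised
with a stage tag.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .barcode import alignment_stats, distance_matrix, read_alignment
from .bootstrap import BootstrapConfig, clade_support
from .cluster import upgma
from .errors import GermdivError, ValidationError
from .marker import read_band_matrix, summary_table
from .ordination import pcoa
from .similarity import similarity_matrix, similarity_to_distance
from .simulate import (
    MarkerSimConfig,
    SeqSimConfig,
    TraitSimConfig,
    simulate_alignment,
    simulate_band_matrix,
    simulate_trait_matrix,
)
from .traits import encode_traits, load_alfalfa_traits, read_codebook, read_trait_table, trait_pipeline

log = logging.getLogger("germdiv")

_TOP_KEYS = {"seed", "outdir", "markers", "barcode", "traits"}
_MARKER_KEYS = {"matrix", "simulate", "pic_variant", "coefficient", "transform"}
_BARCODE_KEYS = {"alignment", "simulate", "model", "deletion", "bootstrap"}
_TRAIT_KEYS = {"table", "codebook", "bundled", "simulate"}


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "germdiv_out"
    markers: dict | None = None
    barcode: dict | None = None
    traits: dict | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        for section, allowed in (
            ("markers", _MARKER_KEYS), ("barcode", _BARCODE_KEYS), ("traits", _TRAIT_KEYS)
        ):
            sub = raw.get(section) or {}
            bad = set(sub) - allowed
            if bad:
                raise ValidationError(f"unknown {section} config key(s): {sorted(bad)}")
        return cls(**raw)


@dataclass
class RunResult:
    outdir: Path
    outputs: list[str]
    warnings: list[str] = field(default_factory=list)


def _write(path: Path, text: str, created: list[Path]) -> None:
    path.write_text(text, encoding="utf-8")
    created.append(path)


def run_pipeline(cfg: RunConfig) -> RunResult:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    warnings: list[str] = []
    stage = "setup"
    try:
        if cfg.markers is not None:
            stage = "markers"
            t0 = time.perf_counter()
            _run_markers(cfg, outdir, created, warnings)
            log.info("markers stage: %.2fs", time.perf_counter() - t0)
        if cfg.barcode is not None:
            stage = "barcode"
            t0 = time.perf_counter()
            _run_barcode(cfg, outdir, created, warnings)
            log.info("barcode stage: %.2fs", time.perf_counter() - t0)
        if cfg.traits is not None:
            stage = "traits"
            t0 = time.perf_counter()
            _run_traits(cfg, outdir, created, warnings)
            log.info("traits stage: %.2fs", time.perf_counter() - t0)
        stage = "manifest"
        manifest = {
            "package": "germdiv",
            "version": __version__,
            "seed": cfg.seed,
            "config": {
                "seed": cfg.seed,
                "outdir": str(cfg.outdir),
                "markers": cfg.markers,
                "barcode": cfg.barcode,
                "traits": cfg.traits,
            },
            "outputs": sorted(p.name for p in created),
            "warnings": warnings,
        }
        _write(outdir / "manifest.json", json.dumps(manifest, indent=2) + "\n", created)
    except Exception as exc:
        for p in created:
            p.unlink(missing_ok=True)
        raise GermdivError(f"[{stage}] {exc}") from exc
    return RunResult(outdir, sorted(p.name for p in created), warnings)


def _run_markers(cfg: RunConfig, outdir: Path, created: list[Path], warnings: list[str]) -> None:
    opts = cfg.markers
    if opts.get("simulate"):
        matrix = simulate_band_matrix(MarkerSimConfig(seed=cfg.seed))
    else:
        matrix = read_band_matrix(opts["matrix"])
    table = summary_table(matrix, opts.get("pic_variant", "pattern_diversity"))
    _write(outdir / "markers_summary.tsv", table.to_csv(sep="\t", index=False), created)
    S = similarity_matrix(matrix, coefficient=opts.get("coefficient", "dice"))
    warnings.extend(S.warnings)
    _write(outdir / "markers_similarity.tsv",
           S.to_frame().to_csv(sep="\t", float_format="%.6f"), created)
    D = similarity_to_distance(S, opts.get("transform", "one_minus_s"))
    _write(outdir / "markers_distance.tsv",
           D.to_frame().to_csv(sep="\t", float_format="%.6f"), created)
    _write(outdir / "markers_upgma.nwk", upgma(D).to_newick() + "\n", created)
    ord_ = pcoa(D)
    warnings.extend(ord_.warnings)
    _write(outdir / "markers_pcoa.tsv",
           ord_.coordinates.to_csv(sep="\t", float_format="%.6f"), created)


def _run_barcode(cfg: RunConfig, outdir: Path, created: list[Path], warnings: list[str]) -> None:
    opts = cfg.barcode
    if opts.get("simulate"):
        sim = opts["simulate"] if isinstance(opts["simulate"], dict) else {}
        aln = simulate_alignment(SeqSimConfig(
            length=sim.get("length", 700),
            missing_fraction=sim.get("missing_fraction", 0.05),
            seed=cfg.seed,
        ))
    else:
        aln = read_alignment(opts["alignment"])
    stats = alignment_stats(aln).report()
    _write(outdir / "barcode_stats.tsv",
           "\t".join(stats) + "\n" + "\t".join(str(v) for v in stats.values()) + "\n",
           created)
    model = opts.get("model", "jc69")
    deletion = opts.get("deletion", "pairwise")
    D = distance_matrix(aln, model, deletion)
    _write(outdir / "barcode_distances.phy", D.to_phylip(), created)
    tree = upgma(D)
    boot = opts.get("bootstrap") or {}
    if boot:
        bcfg = BootstrapConfig(
            n_replicates=boot.get("n_replicates", 500),
            seed=cfg.seed, model=model, deletion=deletion,
        )
        support = clade_support(tree, aln, bcfg)
        support.annotate(tree)
        if support.n_replicates_skipped:
            warnings.append(
                f"bootstrap: {support.n_replicates_skipped} saturated replicate(s) skipped"
            )
        _write(outdir / "barcode_upgma.nwk", tree.to_newick(with_support=True) + "\n", created)
    else:
        _write(outdir / "barcode_upgma.nwk", tree.to_newick() + "\n", created)


def _run_traits(cfg: RunConfig, outdir: Path, created: list[Path], warnings: list[str]) -> None:
    opts = cfg.traits
    if opts.get("simulate"):
        matrix = simulate_trait_matrix(TraitSimConfig(seed=cfg.seed))
    elif opts.get("bundled"):
        matrix, _, _ = load_alfalfa_traits()
    else:
        codebook = read_codebook(opts["codebook"])
        matrix = encode_traits(read_trait_table(opts["table"]), codebook)
    res = trait_pipeline(matrix)
    warnings.extend(res.pca.warnings + res.pcoa.warnings)
    _write(outdir / "traits_distance.tsv",
           res.distances.to_frame().to_csv(sep="\t", float_format="%.6f"), created)
    _write(outdir / "traits_upgma.nwk", res.tree.to_newick() + "\n", created)
    _write(outdir / "traits_pca_scores.tsv",
           res.pca.coordinates.to_csv(sep="\t", float_format="%.6f"), created)
    _write(outdir / "traits_pca_loadings.tsv",
           res.pca.loadings.to_csv(sep="\t", float_format="%.6f"), created)
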