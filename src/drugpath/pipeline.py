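"""End-to-end orchestration: inputs → pathways → similarities → predictions.

The pipeline is a thin deterministic driver over the library modules; given
identical inputs and configuration it produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io, pathways, similarity, transfer
from .errors import ConfigurationError, UntestableThresholdError
from .synthetic import FixtureBundle

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "BundleAnalysis",
    "run_pipeline",
    "run_on_bundle",
    "analyze_bundle",
]


@dataclass
class PipelineConfig:
    network: str
    ppi: str
    seeds: str
    go_catalog: str
    kegg_catalog: str
    known_indications: str | None = None
    reference_indications: str | None = None
    known_side_effects: str | None = None
    reference_side_effects: str | None = None
    out_dir: str = "out"
    terminal_types: list[str] = field(
        default_factory=lambda: sorted(io.DEFAULT_TERMINAL_TYPES)
    )
    max_paths: int = 100
    max_ppi_prefix: int = 3
    alpha: float = 0.01
    grid: list[float] = field(default_factory=transfer.default_grid)
    expand_complexes: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate_inputs(self) -> None:
        for name in ("network", "ppi", "seeds", "go_catalog", "kegg_catalog",
                     "known_indications", "reference_indications",
                     "known_side_effects", "reference_side_effects"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input file for {name!r} does not exist: {p}")
        if not (0 < self.alpha <= 1):
            raise ConfigurationError("alpha must lie in (0, 1]")


@dataclass
class PipelineResult:
    out_dir: Path
    drug_pathways: dict[str, pathways.DrugPathway]
    matrices: dict[str, similarity.SimilarityMatrix]
    predictions: dict[str, transfer.PredictionSet]
    scans: dict[str, dict[str, transfer.ThresholdScan]]
    enrichment: dict[str, dict]


def _predict_kind(
    kind: str,
    matrices: dict[str, similarity.SimilarityMatrix],
    known: io.AssociationSet,
    reference: io.AssociationSet,
    grid: list[float],
) -> tuple[transfer.PredictionSet | None, dict[str, transfer.ThresholdScan], dict]:
    phenotypes = known.phenotypes() | reference.phenotypes()
    try:
        prediction, scans = transfer.predict_associations(
            matrices, known, reference, phenotypes, grid
        )
    except UntestableThresholdError as exc:
        log.warning("%s prediction untestable: %s", kind, exc)
        return None, {}, {"error": str(exc)}
    report: dict = {"n_predictions": len(prediction.pairs)}
    if prediction.pairs:
        try:
            enr = transfer.candidate_enrichment(
                prediction.pairs, reference, matrices["gene"].drugs, phenotypes, known
            )
            report["enrichment_vs_reference"] = {
                "p_value": enr.p_value,
                "odds_ratio": enr.odds_ratio,
                "table": dataclasses.asdict(enr.table),
            }
        except (UntestableThresholdError, ValueError) as exc:
            report["enrichment_vs_reference"] = {"error": str(exc)}
    return prediction, scans, report


def _write_predictions(
    path: Path,
    prediction: transfer.PredictionSet,
    matrices: dict[str, similarity.SimilarityMatrix],
    known: io.AssociationSet,
) -> None:
    """Prediction TSV with, per pair, the maximum similarity to any drug the
    phenotype was transferred from (one column per measure)."""
    lines = ["drug_id\tphenotype_id\tsim_gene\tsim_go\tsim_kegg"]
    for d, ph in sorted(prediction.pairs):
        sims = []
        for m in similarity.MEASURES:
            mat = matrices[m]
            donors = [
                mat.get(src, d)
                for src in mat.drugs
                if src != d and (src, ph) in known.pairs
            ]
            sims.append(max(donors) if donors else 0.0)
        lines.append(
            "\t".join([d, ph] + [f"{s:.6f}" for s in sims])
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run the full pipeline and write every artifact under ``cfg.out_dir``."""
    cfg.validate_inputs()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "pathways").mkdir(exist_ok=True)

    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("drugpath")
    root.addHandler(fh)
    try:
        net = io.read_curated_network(cfg.network, frozenset(cfg.terminal_types))
        ppi = io.read_ppi_network(cfg.ppi)
        seeds = io.read_drug_seed_sets(cfg.seeds)
        catalogs = {
            "go": io.read_gene_sets(cfg.go_catalog),
            "kegg": io.read_gene_sets(cfg.kegg_catalog),
        }
        path_cfg = pathways.PathConfig(
            max_paths=cfg.max_paths,
            max_ppi_prefix=cfg.max_ppi_prefix,
            expand_complexes=cfg.expand_complexes,
        )
        drug_pathways: dict[str, pathways.DrugPathway] = {}
        for s in seeds:
            pw = pathways.build_drug_pathway(s, net, ppi, path_cfg)
            drug_pathways[s.drug_id] = pw
            pathways.write_pathway(pw, out / "pathways")
        log.info("built %d pathways (%d empty)",
                 len(drug_pathways), sum(p.is_empty for p in drug_pathways.values()))

        uni = similarity.gene_universe(net, ppi)
        matrices = {
            m: similarity.similarity_matrix(
                list(drug_pathways.values()), m, net, catalogs, uni,
                alpha=cfg.alpha, expand_complexes=cfg.expand_complexes,
            )
            for m in similarity.MEASURES
        }
        for m, mat in matrices.items():
            mat.write_tsv(out / f"similarity_{m}.tsv")

        predictions: dict[str, transfer.PredictionSet] = {}
        scans: dict[str, dict[str, transfer.ThresholdScan]] = {}
        report: dict = {"schema_version": 1, "kinds": {}}
        kinds = {
            "indication": (cfg.known_indications, cfg.reference_indications),
            "side_effect": (cfg.known_side_effects, cfg.reference_side_effects),
        }
        for kind, (known_path, ref_path) in kinds.items():
            if known_path is None or ref_path is None:
                continue
            known = io.read_association_table(known_path, kind)
            reference = io.read_association_table(ref_path, kind)
            prediction, kind_scans, kind_report = _predict_kind(
                kind, matrices, known, reference, cfg.grid
            )
            kind_report["thresholds"] = (
                {m: s.chosen for m, s in kind_scans.items()} if kind_scans else {}
            )
            kind_report["scans"] = {m: s.to_dict() for m, s in kind_scans.items()}
            report["kinds"][kind] = kind_report
            if prediction is None:
                prediction = transfer.PredictionSet(set(), {m: set() for m in similarity.MEASURES}, {})
            predictions[kind] = prediction
            scans[kind] = kind_scans
            _write_predictions(
                out / f"predictions_{kind}.tsv", prediction, matrices, known
            )
            if not prediction.pairs:
                log.warning("%s: 0 predictions", kind)

        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        return PipelineResult(
            out_dir=out,
            drug_pathways=drug_pathways,
            matrices=matrices,
            predictions=predictions,
            scans=scans,
            enrichment={k: v for k, v in report["kinds"].items()},
        )
    finally:
        root.removeHandler(fh)
        fh.close()


@dataclass
class BundleAnalysis:
    """In-memory pipeline pass over a fixture bundle (no files written)."""

    bundle: FixtureBundle
    drug_pathways: dict[str, pathways.DrugPathway]
    matrices: dict[str, similarity.SimilarityMatrix]
    predictions: dict[str, transfer.PredictionSet]
    scans: dict[str, dict[str, transfer.ThresholdScan]]


def analyze_bundle(
    bundle: FixtureBundle,
    grid: list[float] | None = None,
    path_config: pathways.PathConfig | None = None,
    alpha: float = 0.01,
) -> BundleAnalysis:
    """Build pathways, similarity matrices and predictions for a bundle."""
    path_cfg = path_config or pathways.PathConfig()
    drug_pathways = {
        s.drug_id: pathways.build_drug_pathway(s, bundle.curated, bundle.ppi, path_cfg)
        for s in bundle.seeds
    }
    uni = similarity.gene_universe(bundle.curated, bundle.ppi)
    catalogs = {"go": bundle.go_catalog, "kegg": bundle.kegg_catalog}
    matrices = {
        m: similarity.similarity_matrix(
            list(drug_pathways.values()), m, bundle.curated, catalogs, uni, alpha=alpha
        )
        for m in similarity.MEASURES
    }
    grid = grid if grid is not None else transfer.default_grid()
    predictions: dict[str, transfer.PredictionSet] = {}
    scans: dict[str, dict[str, transfer.ThresholdScan]] = {}
    kinds = {
        "indication": (bundle.known_indications, bundle.reference_indications,
                       bundle.indication_phenotypes),
        "side_effect": (bundle.known_side_effects, bundle.reference_side_effects,
                        bundle.side_effect_phenotypes),
    }
    for kind, (known, reference, vocab) in kinds.items():
        try:
            prediction, kind_scans = transfer.predict_associations(
                matrices, known, reference, set(vocab), grid
            )
        except UntestableThresholdError as exc:
            log.warning("%s prediction untestable: %s", kind, exc)
            prediction = transfer.PredictionSet(
                set(), {m: set() for m in similarity.MEASURES}, {}
            )
            kind_scans = {}
        predictions[kind] = prediction
        scans[kind] = kind_scans
    return BundleAnalysis(bundle, drug_pathways, matrices, predictions, scans)


def run_on_bundle(bundle: FixtureBundle, out_dir: str | Path, **overrides) -> PipelineResult:
    """Write a fixture bundle to disk and run the pipeline on it."""
    from .synthetic import BUNDLE_FILES, write_fixture_bundle

    out = Path(out_dir)
    fixtures = out / "fixtures"
    fixtures.mkdir(parents=True, exist_ok=True)
    write_fixture_bundle(bundle, fixtures)
    cfg = PipelineConfig(
        network=str(fixtures / BUNDLE_FILES["curated"]),
        ppi=str(fixtures / BUNDLE_FILES["ppi"]),
        seeds=str(fixtures / BUNDLE_FILES["seeds"]),
        go_catalog=str(fixtures / BUNDLE_FILES["go"]),
        kegg_catalog=str(fixtures / BUNDLE_FILES["kegg"]),
        known_indications=str(fixtures / BUNDLE_FILES["known_indications"]),
        reference_indications=str(fixtures / BUNDLE_FILES["reference_indications"]),
        known_side_effects=str(fixtures / BUNDLE_FILES["known_side_effects"]),
        reference_side_effects=str(fixtures / BUNDLE_FILES["reference_side_effects"]),
        out_dir=str(out / "results"),
        **overrides,
    )
    return run_pipeline(cfg)
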