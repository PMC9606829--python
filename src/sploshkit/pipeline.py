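"""Pipeline orchestration: configuration, stage wiring, and audit reports.

``run_pipeline`` executes curate -> SPLoSH(20) -> relationships ->
classification -> SPLoSH(5) -> PCA -> outlier flags, writing every stage
table plus a run log (seed, thresholds, versions).  All randomness is
derived from one global seed by fixed fan-out so re-running a config
reproduces every output byte for byte; the log carries no timestamps for
the same reason.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (ClassifierConfig, classify_panel, results_frame)
from .model import CurationConfig, GenotypePanel, curate
from .ordination import flag_outliers, pca_on_splosh
from .pedigree import RelationshipConfig, relate, relationships_frame
from .segments import SegmentSet, SploshConfig, splosh_matrix

log = logging.getLogger(__name__)

_KNOWN_BLOCKS = {"seed", "out_prefix", "curation", "splosh", "relationships",
                 "classifier", "ordination"}


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    out_prefix: str = "audit"
    curation: CurationConfig = field(default_factory=CurationConfig)
    splosh20: SploshConfig = field(default_factory=SploshConfig)
    splosh5: SploshConfig = field(
        default_factory=lambda: SploshConfig(threshold_cM=5.0))
    relationships: RelationshipConfig = field(default_factory=RelationshipConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    ordination_components: int = 2
    outlier_quantile: float = 0.995

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_BLOCKS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        splosh = raw.get("splosh", {})
        for key in set(splosh) - {"relationship_threshold_cM",
                                  "ordination_threshold_cM",
                                  "error_tolerance", "min_snps_per_segment"}:
            raise ValueError(f"unknown splosh option {key!r}")
        common = {k: splosh[k] for k in ("error_tolerance",
                                         "min_snps_per_segment") if k in splosh}
        cc = raw.get("classifier", {})
        if "flag_band_cM" in cc:
            cc["flag_band_cM"] = tuple(cc["flag_band_cM"])
        ordination = raw.get("ordination", {})
        return cls(
            seed=int(raw.get("seed", 0)),
            out_prefix=str(raw.get("out_prefix", "audit")),
            curation=CurationConfig(**raw.get("curation", {})),
            splosh20=SploshConfig(
                threshold_cM=splosh.get("relationship_threshold_cM", 20.0),
                **common),
            splosh5=SploshConfig(
                threshold_cM=splosh.get("ordination_threshold_cM", 5.0),
                **common),
            relationships=RelationshipConfig(**raw.get("relationships", {})),
            classifier=ClassifierConfig(**cc),
            ordination_components=int(ordination.get("n_components", 2)),
            outlier_quantile=float(ordination.get("quantile", 0.995)),
        )

    def thresholds(self) -> dict:
        return {
            "curation": asdict(self.curation),
            "splosh20": asdict(self.splosh20),
            "splosh5": asdict(self.splosh5),
            "relationships": asdict(self.relationships),
            "classifier": {**asdict(self.classifier),
                           "flag_band_cM": list(self.classifier.flag_band_cM)},
            "ordination": {"n_components": self.ordination_components,
                           "quantile": self.outlier_quantile},
        }


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    import zlib
    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode()) % (2 ** 31)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: PipelineConfig, panel: GenotypePanel,
                 out_dir: str | Path) -> dict[str, Path]:
    """Run the full audit and write all stage tables under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = config.out_prefix
    paths: dict[str, Path] = {}

    def write(name: str, frame: pd.DataFrame, index: bool = False) -> None:
        p = out_dir / f"{prefix}.{name}.csv"
        frame.to_csv(p, index=index)
        paths[name] = p

    stage = "curate"
    try:
        config.classifier.validate_against_map(panel.gmap)
        cured = curate(panel, config.curation)

        stage = "splosh20"
        m20 = splosh_matrix(cured, config.splosh20)
        write("splosh20", m20.to_frame(), index=True)

        stage = "relate"
        calls, codes = relate(cured, m20, config.relationships)
        rel = relationships_frame(calls)
        write("relationships", rel)
        write("unique_genotype_codes",
              pd.DataFrame(sorted(codes.items()), columns=["id", "code"]))

        stage = "classify"
        results, summary = classify_panel(
            cured, config.classifier, config.relationships, config.splosh20,
            splosh20=m20)
        write("classification", results_frame(results))
        write("summary", summary)

        stage = "splosh5"
        m5 = splosh_matrix(cured, config.splosh5)
        write("splosh5", m5.to_frame(), index=True)

        stage = "ordination"
        from .classify import PURE
        pure_ids = [r.id for r in results if r.status == PURE]
        flags = pd.DataFrame(columns=["species", "mahalanobis_sq", "flagged"])
        coords = pd.DataFrame()
        if len(pure_ids) >= 3:
            ordn = pca_on_splosh(m5, pure_ids,
                                 n_components=config.ordination_components)
            coords = ordn.to_frame()
            coords["variance_explained"] = list(
                ordn.variance_explained) + [np.nan] * (len(coords)
                                                       - len(ordn.variance_explained))
            labels = {i: str(cured.metadata.loc[i, "recorded_species"])
                      for i in pure_ids}
            if len(set(labels.values())) >= 2:
                flags = flag_outliers(ordn, labels,
                                      quantile=config.outlier_quantile,
                                      n_components=config.ordination_components)
        write("pca_coordinates", coords, index=True)
        write("outlier_flags", flags, index=True)
    except Exception as exc:
        log.error("pipeline aborted in stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    log_path = out_dir / f"{prefix}.run_log.json"
    log_path.write_text(json.dumps({
        "sploshkit_version": __version__,
        "seed": config.seed,
        "n_individuals": cured.n_individuals,
        "n_snps": cured.gmap.n_snps,
        "total_cM": cured.gmap.total_cM,
        "thresholds": config.thresholds(),
    }, indent=2, sort_keys=True))
    paths["run_log"] = log_path
    return paths


def render_segment_tracks(segset: SegmentSet, out_path: str | Path) -> Path:
    """Per-chromosome shared-segment track table (BED-like, cM coordinates)."""
    out_path = Path(out_path)
    frame = segset.to_frame()
    frame.to_csv(out_path, sep="\t", index=False, float_format="%.2f")
    return out_path
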