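"""Species-status classification of genebank accessions.

An accession's recorded species label is audited against genotype
evidence, in strict precedence:

1. duplicate of a cultivar, or both identified parents cultivars
   -> ``fully_domestica`` (the whole pedigree is cultivar);
2. one cultivar parent, or any likely cultivar grandparent
   -> ``hybrid``;
3. SPLoSH(20 cM) above 256 cM (10% of the diploid genome) with any single
   cultivar -> ``species_with_domestica_component`` (admixed);
4. SPLoSH between 7.5% and 10% with numerous distinct cultivars
   -> ``flagged_7.5_10`` (noted, not called admixed);
5. otherwise ``pure`` pending the ordination outlier check.

An exotic-component annotation (SPLoSH above 256 cM with a verified
exotic reference panel) can attach to any of the above; when nothing else
fires it becomes the primary status.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import GeneticMap, GenotypePanel
from .pedigree import (DUPLICATE, GRANDPARENT_LEVEL, PARENT_OFFSPRING,
                       RelationshipCall, RelationshipConfig, relate)
from .segments import SploshConfig, SploshMatrix, genome_fraction, splosh_matrix

log = logging.getLogger(__name__)

FULLY_DOMESTICA = "fully_domestica"
HYBRID = "hybrid"
DOMESTICA_COMPONENT = "species_with_domestica_component"
FLAGGED_BAND = "flagged_7.5_10"
EXOTIC_COMPONENT = "exotic_component"
PURE = "pure"
POSSIBLE_OUTLIER = "possible_admixed_outlier"

#: statuses pooled as "hybrid or admixed" in site summaries
_HYBRID_ADMIXED = {HYBRID, DOMESTICA_COMPONENT, FLAGGED_BAND,
                   EXOTIC_COMPONENT, POSSIBLE_OUTLIER}


@dataclass(frozen=True)
class ClassifierConfig:
    component_min_cM: float = 256.0          # 10% of the 2560 cM diploid map
    flag_band_cM: tuple[float, float] = (192.0, 256.0)   # 7.5-10%
    grandparent_min_cM: float = 512.0        # 20%
    exotic_min_cM: float = 256.0
    numerous_min: int = 3                    # "numerous cultivars" in the band

    def __post_init__(self) -> None:
        lo, hi = self.flag_band_cM
        if not 0 <= lo <= hi <= self.component_min_cM:
            raise ValueError("flag band must sit below component_min_cM")
        if min(self.component_min_cM, self.grandparent_min_cM,
               self.exotic_min_cM) < 0:
            raise ValueError("thresholds must be non-negative")

    def validate_against_map(self, gmap: GeneticMap, rtol: float = 0.02
                             ) -> None:
        """Threshold coherence: 10% and 20% of the configured diploid map.

        A small relative tolerance absorbs chromosome-end coverage lost to
        SNP curation; the audit thresholds themselves are nominal-map
        constants (256 and 512 cM on the 1280 cM map).
        """
        diploid = 2.0 * gmap.total_cM
        if not np.isclose(self.component_min_cM, 0.10 * diploid, rtol=rtol):
            raise ValueError(
                f"component_min_cM={self.component_min_cM} is not 10% of the "
                f"{diploid:.0f} cM diploid map")
        if not np.isclose(self.grandparent_min_cM, 0.20 * diploid, rtol=rtol):
            raise ValueError(
                f"grandparent_min_cM={self.grandparent_min_cM} is not 20% of "
                f"the {diploid:.0f} cM diploid map")


@dataclass
class ClassificationResult:
    id: str
    recorded_species: str
    status: str
    duplicate_of: list[str] = field(default_factory=list)
    po_cultivars: list[str] = field(default_factory=list)
    gp_cultivars: list[str] = field(default_factory=list)
    max_cultivar_splosh_cM: float = 0.0
    max_cultivar_fraction: float = 0.0
    flag_band_count: int = 0
    exotic: bool = False
    exotic_splosh_cM: float = 0.0


def verified_exotic_panel(exotic_ids: list[str], cultivar_ids: list[str],
                          splosh20: SploshMatrix, config: ClassifierConfig
                          ) -> list[str]:
    """Exotic reference members must lack significant cultivar SPLoSH."""
    out = []
    ceiling = config.flag_band_cM[0]
    for e in exotic_ids:
        best = max((splosh20.value(e, c) for c in cultivar_ids), default=0.0)
        if best > ceiling:
            warnings.warn(f"exotic panel member {e!r} shares {best:.0f} cM "
                          "with cultivars; excluded from the exotic reference")
        else:
            out.append(e)
    return out


def exotic_component_check(acc: str, exotic_panel_ids: list[str],
                           splosh20: SploshMatrix,
                           config: ClassifierConfig = ClassifierConfig()
                           ) -> tuple[bool, float]:
    if not exotic_panel_ids:
        warnings.warn("empty exotic reference panel; exotic check disabled")
        return False, 0.0
    best = max(splosh20.value(acc, e) for e in exotic_panel_ids)
    return best > config.exotic_min_cM, best


def classify_accession(acc: str, relationships: list[RelationshipCall],
                       splosh20: SploshMatrix, panel: GenotypePanel,
                       config: ClassifierConfig = ClassifierConfig(),
                       exotic_panel_ids: list[str] | None = None
                       ) -> ClassificationResult:
    """Apply the decision tree to one accession (see module docstring)."""
    if not splosh20.contains(acc):
        raise KeyError(f"accession {acc!r} absent from the SPLoSH matrix")
    cultivars = set(panel.group_ids("cultivar"))
    if not cultivars:
        raise ValueError("cultivar reference group is empty")

    res = ClassificationResult(
        acc, str(panel.metadata.loc[acc, "recorded_species"]), PURE)
    for call in relationships:
        if acc not in call.pair:
            continue
        other = call.pair[1] if call.pair[0] == acc else call.pair[0]
        if other not in cultivars:
            continue
        if call.type == DUPLICATE:
            res.duplicate_of.append(other)
        elif call.type == PARENT_OFFSPRING:
            res.po_cultivars.append(other)
        elif call.type == GRANDPARENT_LEVEL:
            res.gp_cultivars.append(other)

    cult_splosh = {c: splosh20.value(acc, c) for c in cultivars if c != acc}
    if cult_splosh:
        best = max(cult_splosh, key=cult_splosh.get)  # type: ignore[arg-type]
        res.max_cultivar_splosh_cM = cult_splosh[best]
        res.max_cultivar_fraction = genome_fraction(cult_splosh[best],
                                                    panel.gmap)
    lo, hi = config.flag_band_cM
    res.flag_band_count = sum(1 for v in cult_splosh.values() if lo <= v <= hi)

    if res.duplicate_of or len(res.po_cultivars) >= 2:
        res.status = FULLY_DOMESTICA
    elif res.po_cultivars or res.gp_cultivars:
        res.status = HYBRID
    elif res.max_cultivar_splosh_cM > config.component_min_cM:
        res.status = DOMESTICA_COMPONENT
    elif res.flag_band_count >= config.numerous_min:
        res.status = FLAGGED_BAND

    if exotic_panel_ids:
        res.exotic, res.exotic_splosh_cM = exotic_component_check(
            acc, exotic_panel_ids, splosh20, config)
        if res.exotic and res.status == PURE:
            res.status = EXOTIC_COMPONENT
    return res


def classify_panel(panel: GenotypePanel,
                   config: ClassifierConfig = ClassifierConfig(),
                   relationship_config: RelationshipConfig = RelationshipConfig(),
                   splosh_config: SploshConfig = SploshConfig(),
                   splosh20: SploshMatrix | None = None
                   ) -> tuple[list[ClassificationResult], pd.DataFrame]:
    """Classify every non-reference accession of a panel.

    Reference groups (``cultivar`` and ``exotic`` metadata) are evidence;
    accessions in the remaining groups are audited.  Returns the per-
    accession results and a site/species summary table.
    """
    config.validate_against_map(panel.gmap)
    if splosh20 is None:
        splosh20 = splosh_matrix(panel, splosh_config)
    relationships, _ = relate(panel, splosh20, relationship_config)
    cultivars = set(panel.group_ids("cultivar"))
    exotic = verified_exotic_panel(panel.group_ids("exotic"), sorted(cultivars),
                                   splosh20, config) \
        if panel.group_ids("exotic") else []
    audited = [i for i in panel.ids
               if i not in cultivars and i not in set(panel.group_ids("exotic"))]
    results = [classify_accession(a, relationships, splosh20, panel, config,
                                  exotic) for a in audited]
    return results, summarize(results)


def results_frame(results: list[ClassificationResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "id": r.id, "recorded_species": r.recorded_species, "status": r.status,
        "duplicate_of": ";".join(r.duplicate_of),
        "po_cultivars": ";".join(r.po_cultivars),
        "gp_cultivars": ";".join(r.gp_cultivars),
        "max_cultivar_splosh_cM": round(r.max_cultivar_splosh_cM, 2),
        "max_cultivar_fraction": round(r.max_cultivar_fraction, 4),
        "flag_band_count": r.flag_band_count,
        "exotic": r.exotic,
        "exotic_splosh_cM": round(r.exotic_splosh_cM, 2),
    } for r in results])


def summarize(results: list[ClassificationResult],
              by: str = "recorded_species") -> pd.DataFrame:
    """Per-label composition: n and % pure / hybrid-admixed / fully cultivar."""
    rows: dict[str, dict[str, int]] = {}
    for r in results:
        key = r.recorded_species if by == "recorded_species" else by
        d = rows.setdefault(key, {"n": 0, "n_pure": 0, "n_hybrid_admixed": 0,
                                  "n_cultivar": 0})
        d["n"] += 1
        if r.status == PURE:
            d["n_pure"] += 1
        elif r.status == FULLY_DOMESTICA:
            d["n_cultivar"] += 1
        elif r.status in _HYBRID_ADMIXED:
            d["n_hybrid_admixed"] += 1
    table = pd.DataFrame(
        [{"label": k, **v} for k, v in sorted(rows.items())])
    if len(table):
        for col in ("pure", "hybrid_admixed", "cultivar"):
            table[f"pct_{col}"] = (100.0 * table[f"n_{col}"] / table["n"]).round(1)
    else:
        table = pd.DataFrame(columns=["label", "n", "n_pure", "n_hybrid_admixed",
                                      "n_cultivar", "pct_pure",
                                      "pct_hybrid_admixed", "pct_cultivar"])
    return table
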