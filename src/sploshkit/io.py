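"""Reading and writing genotype panels.

Two on-disk dialects are supported:

* a human-auditable TSV (rows = SNPs, columns = individuals, calls in
  ``AA``/``AB``/``BB``/``--``) with a companion map TSV
  (``snp_id  chrom  pos_cM``), and
* PLINK text ``.ped``/``.map`` (the map's third column carries cM; the
  fourth, physical position, is unused and written as 0; missing calls are
  ``0 0``).

Both are paired with a metadata CSV (``id,recorded_species,reference_group``).
SNPs present in only one of genotype file and map are dropped (count
logged); zero overlap is fatal.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (CALL_TO_TEXT, HET, HOM_A, HOM_B, MISSING, TEXT_TO_CALL,
                    FormatError, GeneticMap, GenotypePanel)

log = logging.getLogger(__name__)

_PED_ALLELES = {HOM_A: ("A", "A"), HET: ("A", "B"),
                HOM_B: ("B", "B"), MISSING: ("0", "0")}


def _read_map(map_path: str | Path) -> GeneticMap:
    path = Path(map_path)
    if path.suffix == ".map":  # PLINK: chrom snp_id cM pos
        try:
            tab = pd.read_csv(path, sep=r"\s+", header=None,
                              names=["chrom", "snp_id", "pos_cM", "bp"])
        except Exception as exc:  # pragma: no cover - pandas error detail
            raise FormatError(f"cannot parse PLINK map {path}: {exc}") from exc
        return GeneticMap(tab[["snp_id", "chrom", "pos_cM"]])
    tab = pd.read_csv(path, sep="\t")
    missing = {"snp_id", "chrom", "pos_cM"} - set(tab.columns)
    if missing:
        raise FormatError(f"{path}: map TSV lacks columns {sorted(missing)}")
    return GeneticMap(tab)


def _read_metadata(metadata_path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(metadata_path, dtype=str)
    missing = {"id", "recorded_species", "reference_group"} - set(meta.columns)
    if missing:
        raise FormatError(
            f"{metadata_path}: metadata lacks columns {sorted(missing)}")
    return meta.set_index("id")


def _read_tsv_calls(path: Path) -> tuple[list[str], list[str], np.ndarray]:
    """Returns (snp_ids, individual_ids, SNPs x individuals call codes)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "snp_id":
            raise FormatError(f"{path}:1: expected header starting 'snp_id'")
        ids = header[1:]
        snp_ids, rows = [], []
        for ln, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(ids) + 1:
                raise FormatError(f"{path}:{ln}: expected {len(ids) + 1} "
                                  f"fields, got {len(fields)}")
            snp_ids.append(fields[0])
            try:
                rows.append([TEXT_TO_CALL[c] for c in fields[1:]])
            except KeyError as exc:
                raise FormatError(f"{path}:{ln}: bad call {exc.args[0]!r}") from exc
    calls = (np.array(rows, dtype=np.int8) if rows
             else np.empty((0, len(ids)), dtype=np.int8))
    return snp_ids, ids, calls


def _read_ped_calls(path: Path) -> tuple[list[str], np.ndarray]:
    """Returns (individual_ids, individuals x SNPs call codes)."""
    ids, rows = [], []
    pair_to_call = {("A", "A"): HOM_A, ("A", "B"): HET, ("B", "A"): HET,
                    ("B", "B"): HOM_B, ("0", "0"): MISSING}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 6 or (len(fields) - 6) % 2:
                raise FormatError(f"{path}:{ln}: malformed ped record")
            ids.append(fields[1])
            alleles = fields[6:]
            try:
                rows.append([pair_to_call[(alleles[i], alleles[i + 1])]
                             for i in range(0, len(alleles), 2)])
            except KeyError as exc:
                raise FormatError(
                    f"{path}:{ln}: bad allele pair {exc.args[0]!r}") from exc
    n_snps = len(rows[0]) if rows else 0
    calls = (np.array(rows, dtype=np.int8) if rows
             else np.empty((0, n_snps), dtype=np.int8))
    return ids, calls


def load_panel(genotype_path: str | Path, map_path: str | Path,
               metadata_path: str | Path) -> GenotypePanel:
    """Load a panel; SNPs are returned in (chrom, pos_cM, snp_id) order.

    The genotype file dialect is chosen by extension (``.ped`` = PLINK,
    anything else = the TSV dialect).  SNPs present in only one of the
    genotype file and the map are dropped with a logged count.
    """
    genotype_path = Path(genotype_path)
    gmap = _read_map(map_path)
    meta = _read_metadata(metadata_path)

    if genotype_path.suffix == ".ped":
        ids, calls = _read_ped_calls(genotype_path)
        snp_ids = list(gmap.snp_ids)
        if calls.shape[1] != len(snp_ids):
            raise FormatError(
                f"{genotype_path}: {calls.shape[1]} SNPs per record but map "
                f"has {len(snp_ids)}")
    else:
        snp_ids, ids, snp_major = _read_tsv_calls(genotype_path)
        calls = snp_major.T

    map_set = set(gmap.snp_ids)
    in_map = [i for i, s in enumerate(snp_ids) if s in map_set]
    n_dropped = (len(snp_ids) - len(in_map)) + (gmap.n_snps - len(in_map))
    if not in_map:
        raise FormatError("no SNPs shared between genotype file and map")
    if n_dropped:
        log.info("load_panel: dropped %d SNPs absent from map or genotypes",
                 n_dropped)
    shared = {snp_ids[i] for i in in_map}
    gmap = gmap.subset(np.flatnonzero(np.isin(gmap.snp_ids, list(shared))))
    col_of = {s: i for i, s in enumerate(snp_ids)}
    calls = calls[:, [col_of[s] for s in gmap.snp_ids]]  # map order
    meta = meta.reindex(ids).fillna(
        {"recorded_species": "unknown", "reference_group": "unknown"})
    meta.index.name = "id"
    return GenotypePanel(gmap, meta, calls)


def save_panel(panel: GenotypePanel, genotype_path: str | Path,
               map_path: str | Path, metadata_path: str | Path
               ) -> tuple[Path, Path, Path]:
    """Write a panel; dialect chosen by genotype extension (.ped = PLINK)."""
    genotype_path, map_path = Path(genotype_path), Path(map_path)
    metadata_path = Path(metadata_path)
    gmap = panel.gmap
    if genotype_path.suffix == ".ped":
        with open(map_path, "w") as fh:
            for s, c, p in zip(gmap.snp_ids, gmap.chrom_of, gmap.positions):
                fh.write(f"{c}\t{s}\t{p:.6f}\t0\n")
        with open(genotype_path, "w") as fh:
            for iid in panel.ids:
                row = panel.genotypes(iid)
                alleles = " ".join(" ".join(_PED_ALLELES[int(g)]) for g in row)
                sep = " " if len(row) else ""
                fh.write(f"{iid} {iid} 0 0 0 -9{sep}{alleles}\n")
    else:
        gmap.table.to_csv(map_path, sep="\t", index=False)
        with open(genotype_path, "w") as fh:
            fh.write("\t".join(["snp_id", *panel.ids]) + "\n")
            for j, snp in enumerate(gmap.snp_ids):
                calls = [CALL_TO_TEXT[int(g)] for g in panel.calls[:, j]]
                fh.write("\t".join([snp, *calls]) + "\n")
    panel.metadata.to_csv(metadata_path, index_label="id")
    return genotype_path, map_path, metadata_path
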