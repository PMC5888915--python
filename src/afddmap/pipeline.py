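"""End-to-end orchestration: read -> filter -> compare -> group -> map.

Runs the full pooled-sequencing mapping workflow with a YAML-configurable
parameter set, writing every intermediate table plus a manifest that records
the tool version, parameters, input checksums and per-stage status, so a run
is reproducible from its output directory alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .density import (
    DEFAULT_AFDD_MIN,
    DEFAULT_BIN_SIZE,
    DEFAULT_MAFD_BAND,
    DEFAULT_WINDOW,
    DEFAULT_Z_CUTOFF,
    MappingResult,
    afddd_map,
    mafd_map,
)
from .filters import FilterConfig, filter_confidence, filter_primary
from .segregation import ZygosityBands, group_common_variants, site_allele_counts
from .variant_io import (
    GenomeLayout,
    Membership,
    match_pools,
    read_pool_table,
    read_pool_vcf,
    write_pool_table,
    write_regions_bed,
)

__all__ = ["PipelineConfig", "PipelineError", "ConfigError", "DataError",
           "run_pipeline"]

log = logging.getLogger(__name__)

STAGES = ["read", "filter_primary", "filter_confidence", "compare", "groups",
          "mafd", "afddd"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Invalid or inconsistent input data (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    mutant_path: str
    wildtype_path: str
    out_dir: str
    layout: GenomeLayout
    filters: FilterConfig = field(default_factory=FilterConfig)
    bands: ZygosityBands = field(default_factory=ZygosityBands)
    mafd_band: tuple[float, float] = DEFAULT_MAFD_BAND
    afdd_min: float = DEFAULT_AFDD_MIN
    window: int = DEFAULT_WINDOW
    bin_size: int = DEFAULT_BIN_SIZE
    z_cutoff: float = DEFAULT_Z_CUTOFF
    reference_fasta: str | None = None
    seed: int = 0
    log_level: str = "INFO"
    force: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except OSError as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        try:
            raw["layout"] = GenomeLayout(
                [(str(n), int(l)) for n, l in raw["layout"]])
            if "filters" in raw:
                raw["filters"] = FilterConfig(**raw["filters"])
            if "bands" in raw:
                raw["bands"] = ZygosityBands(**raw["bands"])
            if "mafd_band" in raw:
                raw["mafd_band"] = tuple(raw["mafd_band"])
            return cls(**raw)
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid config {path}: {exc}") from exc

    def parameters(self) -> dict:
        return {
            "mafd_band": list(self.mafd_band),
            "afdd_min": self.afdd_min,
            "window": self.window,
            "bin_size": self.bin_size,
            "z_cutoff": self.z_cutoff,
            "het_band": [self.bands.het_min, self.bands.het_max],
            "filters": {
                k: (sorted(v) if isinstance(v, frozenset) else v)
                for k, v in vars(self.filters).items()
            },
            "seed": self.seed,
        }


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_pool(path: str, label: str, layout: GenomeLayout):
    p = Path(path)
    if not p.exists():
        raise DataError(f"input file not found: {p}")
    if p.suffix in (".vcf", ".gz", ".bcf"):
        return read_pool_vcf(p, label, layout)
    return read_pool_table(p, label)


def _write_mapping(result: MappingResult, out_dir: Path, layout: GenomeLayout,
                   params: str) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    header = f"# afddmap {__version__} | {params}\n"
    for name, frame in (("profile.tsv", result.profile),
                        ("bins.tsv", result.bins)):
        with open(out_dir / name, "w") as fh:
            fh.write(header)
            frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    write_regions_bed(result.region_rows(), out_dir / "regions.bed", layout,
                      parameters=params)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full workflow; returns the run directory.

    Never silently overwrites a previous run: an existing manifest aborts
    unless ``config.force`` is set.  A stage failure writes a partial
    manifest naming the stage before re-raising.
    """
    out = Path(config.out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not config.force:
        raise ConfigError(
            f"{out} already holds a run (manifest.json); use force to overwrite")
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "tool": "afddmap",
        "version": __version__,
        "parameters": config.parameters(),
        "inputs": {},
        "stages": [],
    }

    def _done(stage: str, **info) -> None:
        manifest["stages"].append({"name": stage, "status": "complete", **info})

    def _fail(stage: str, exc: Exception):
        manifest["stages"].append({"name": stage, "status": "failed",
                                   "error": str(exc)})
        manifest_path.write_text(json.dumps(manifest, indent=2))
        raise PipelineError(stage, str(exc)) from exc

    params_str = json.dumps(config.parameters(), sort_keys=True)

    # read
    try:
        for p in (config.mutant_path, config.wildtype_path):
            if not Path(p).exists():
                raise DataError(f"input file not found: {p}")
            manifest["inputs"][str(p)] = _sha256(p)
        mutant = _read_pool(config.mutant_path, "mutant", config.layout)
        wildtype = _read_pool(config.wildtype_path, "wildtype", config.layout)
    except Exception as exc:  # noqa: BLE001 - manifest must name the stage
        _fail("read", exc)
    _done("read", mutant_calls=len(mutant), wildtype_calls=len(wildtype))

    reference_context = None
    if config.reference_fasta:
        try:
            reference_context = _load_fasta(config.reference_fasta)
        except Exception as exc:
            _fail("read", exc)

    # primary filter
    try:
        mutant, rep_m = filter_primary(mutant, reference_context, config.filters)
        wildtype, rep_w = filter_primary(wildtype, reference_context,
                                         config.filters)
        (out / "filter_primary_mutant.tsv").write_text(rep_m.to_tsv())
        (out / "filter_primary_wildtype.tsv").write_text(rep_w.to_tsv())
    except Exception as exc:
        _fail("filter_primary", exc)
    _done("filter_primary", mutant_surviving=rep_m.surviving,
          wildtype_surviving=rep_w.surviving)

    # confidence filter
    try:
        mutant, rep_m = filter_confidence(mutant, config.filters)
        wildtype, rep_w = filter_confidence(wildtype, config.filters)
        (out / "filter_confidence_mutant.tsv").write_text(rep_m.to_tsv())
        (out / "filter_confidence_wildtype.tsv").write_text(rep_w.to_tsv())
        write_pool_table(mutant, out / "mutant_filtered.tsv", params_str)
        write_pool_table(wildtype, out / "wildtype_filtered.tsv", params_str)
    except Exception as exc:
        _fail("filter_confidence", exc)
    _done("filter_confidence", mutant_surviving=rep_m.surviving,
          wildtype_surviving=rep_w.surviving)

    # compare
    try:
        joined = match_pools(mutant, wildtype)
        common = [v for v in joined if v.membership is Membership.COMMON]
        mutant_specific = [v.mutant_call for v in joined
                           if v.membership is Membership.MUTANT_SPECIFIC]
        wildtype_specific = [v.wildtype_call for v in joined
                             if v.membership is Membership.WILDTYPE_SPECIFIC]
    except Exception as exc:
        _fail("compare", exc)
    _done("compare", mutant_specific=len(mutant_specific),
          wildtype_specific=len(wildtype_specific), common=len(common))

    # genotype groups
    try:
        counts = site_allele_counts(joined)
        _, summary = group_common_variants(common, config.bands, counts)
        with open(out / "genotype_groups.tsv", "w") as fh:
            fh.write(f"# afddmap {__version__} | {params_str}\n")
            summary.to_csv(fh, sep="\t", index=False, float_format="%.4g")
    except Exception as exc:
        _fail("groups", exc)
    _done("groups")

    # MAFD on mutant-specific variants
    try:
        mafd = mafd_map(mutant_specific, config.layout, band=config.mafd_band,
                        window=config.window, bin_size=config.bin_size,
                        z_cutoff=config.z_cutoff)
        _write_mapping(mafd, out / "mafd", config.layout, params_str)
    except Exception as exc:
        _fail("mafd", exc)
    _done("mafd", selected=mafd.n_selected,
          significant_regions=len(mafd.regions))

    # AFDDD on common variants
    try:
        afddd = afddd_map(common, config.layout, afdd_min=config.afdd_min,
                          window=config.window, bin_size=config.bin_size,
                          z_cutoff=config.z_cutoff)
        _write_mapping(afddd, out / "afddd", config.layout, params_str)
    except Exception as exc:
        _fail("afddd", exc)
    _done("afddd", selected=afddd.n_selected,
          significant_regions=len(afddd.regions))

    manifest_path.write_text(json.dumps(manifest, indent=2))
    return out


def _load_fasta(path: str) -> dict[str, str]:
    """Plain FASTA loader for the reference context (small genomes)."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line)
    return {n: "".join(parts) for n, parts in seqs.items()}
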