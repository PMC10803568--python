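"""Run configuration: one YAML file drives the whole pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .dmr import DmrParams

__all__ = ["RunConfig", "ValidationError"]


class ValidationError(ValueError):
    """Configuration problem detected before any compute."""


@dataclass
class RunConfig:
    genome: str
    annotation: str
    cytosine_reports: dict[str, str]
    counts: str
    outdir: str
    groups: dict[str, str]
    gmt: str | None = None
    seed: int = 0
    # thresholds, mirrored from the analysis conventions
    site_alpha: float = 0.05
    min_depth: int = 5
    collapse_strands: bool = False
    spike_in_contig: str = "lambda_spike"
    promoter_size: int = 2000
    shore_size: int = 2000
    cgi_min_len: int = 200
    cgi_min_gc: float = 0.5
    cgi_min_oe: float = 0.65
    deg_log2fc_cut: float = 1.0
    deg_alpha: float = 0.05
    enrichment_alpha: float = 0.05
    metagene_flank: int = 2000
    metagene_body_bins: int = 60
    metagene_flank_bins: int = 20
    make_plots: bool = False
    dmr: DmrParams = field(default_factory=DmrParams)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: not a mapping")
        dmr = raw.pop("dmr", {})
        try:
            cfg = cls(**raw, dmr=DmrParams(**dmr))
        except TypeError as exc:
            raise ValidationError(str(exc)) from exc
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def validate(self) -> None:
        for label, p in [("genome", self.genome), ("annotation", self.annotation),
                         ("counts", self.counts)]:
            if not Path(p).exists():
                raise ValidationError(f"{label} file not found: {p}")
        if not self.cytosine_reports:
            raise ValidationError("no cytosine reports configured")
        for sample, p in self.cytosine_reports.items():
            if not Path(p).exists():
                raise ValidationError(f"cytosine report for {sample} not found: {p}")
            if sample not in self.groups:
                raise ValidationError(f"sample {sample} missing from the group map")
        if self.gmt is not None and not Path(self.gmt).exists():
            raise ValidationError(f"GMT file not found: {self.gmt}")
        if len(set(self.groups.values())) != 2:
            raise ValidationError("group map must define exactly two groups")
        if not 0 < self.site_alpha < 1 or not 0 < self.deg_alpha < 1:
            raise ValidationError("alpha levels must lie in (0, 1)")
        if self.min_depth < 1:
            raise ValidationError("min_depth must be >= 1")
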