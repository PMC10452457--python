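"""Run configuration: every knob of the pipeline, serializable for provenance."""

from __future__ import annotations

from dataclasses import asdict, dataclass

from ..core import ValidationError

MODES = ("voxel", "surface_closing")
APEX_RULES = ("cavity_tip", "fraction")


@dataclass
class RunConfig:
    """Pipeline configuration; round-trips through :meth:`to_dict`.

    ``apex_rule`` is either ``"cavity_tip"`` or ``"fraction:F"`` with F the
    apex fraction of the shell's axial extent.
    """

    thickness_mm: float = 8.0
    apex_rule: str = "cavity_tip"
    closing_radius_mm: float = 2.0
    mode: str = "voxel"
    flip_rotation: bool = False
    basal_cut_t: float | None = None
    line_step_mm: float = 1.0
    force_orientation: int | None = None
    log_level: str = "INFO"

    # ------------------------------------------------------------------
    def validate(self) -> "RunConfig":
        if self.thickness_mm <= 0:
            raise ValidationError("thickness_mm must be > 0")
        if self.closing_radius_mm < 0:
            raise ValidationError("closing_radius_mm must be >= 0")
        if self.line_step_mm <= 0:
            raise ValidationError("line_step_mm must be > 0")
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        self.apex_rule_tuple()  # raises on malformed rule
        if self.force_orientation not in (None, 1, -1):
            raise ValidationError("force_orientation must be None, +1 or -1")
        return self

    def apex_rule_tuple(self) -> str | tuple[str, float]:
        """Parsed apex rule as consumed by ``region_planes``."""
        if self.apex_rule == "cavity_tip":
            return "cavity_tip"
        if self.apex_rule.startswith("fraction:"):
            try:
                f = float(self.apex_rule.split(":", 1)[1])
            except ValueError as exc:
                raise ValidationError(f"bad apex_rule {self.apex_rule!r}") from exc
            if not 0.0 < f < 1.0:
                raise ValidationError("apex fraction must lie in (0, 1)")
            return ("fraction", f)
        raise ValidationError(
            f"apex_rule must be 'cavity_tip' or 'fraction:F', got {self.apex_rule!r}"
        )

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d).validate()
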