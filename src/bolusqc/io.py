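"""Reading and writing photometric recordings and study designs.

A recording is a two-column CSV (time in seconds, raw sensor intensity in
arbitrary units) produced by a photometric cell watching the outlet of an
injector tube line.  The study design file enumerates the injector
configurations (piston-syringe ``PS`` or roller-pump ``RP``, line filling
volume, maximum injection power, regular or experimental line fitting) and
the injection protocols (contrast-medium type, volume, flow rate, protocol
group) that together index every recording of a bench study.
"""

from __future__ import annotations

import enum
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "CMType",
    "PumpType",
    "LineConfig",
    "ProtocolGroup",
    "TCRecording",
    "InjectionProtocol",
    "InjectorConfig",
    "StudyDesign",
    "RecordingParseError",
    "DesignValidationError",
    "read_recording",
    "write_recording",
    "read_study_design",
    "default_design",
    "expected_injection_time",
    "protocol_in_group",
]

DEFAULT_SAMPLING_HZ = 12.2
WATER_VISCOSITY_MPA_S = 1.0


class CMType(str, enum.Enum):
    """Gadolinium contrast medium. Viscosities at 20 degC (mPa*s)."""

    GADOTERATE = "gadoterate"
    GADOTERIDOL = "gadoteridol"

    @property
    def viscosity_mpa_s(self) -> float:
        return {CMType.GADOTERATE: 3.4, CMType.GADOTERIDOL: 2.0}[self]


class PumpType(str, enum.Enum):
    PS = "PS"  # piston-syringe
    RP = "RP"  # peristaltic roller pump


class LineConfig(str, enum.Enum):
    REGULAR = "regular"
    EXPERIMENTAL = "experimental"


class ProtocolGroup(str, enum.Enum):
    VVOL = "vVol"  # variable volume at constant 5 ml/s flow
    CVOL = "cVol"  # constant 10 ml volume at variable flow
    MVOL = "mVol"  # micro volumes (2 ml)


class RecordingParseError(ValueError):
    """Raised when a recording file cannot be parsed or is inconsistent."""


class DesignValidationError(ValueError):
    """Raised when a study design violates its schema or invariants."""


@dataclass(frozen=True)
class InjectionProtocol:
    protocol_id: str
    cm_type: CMType
    cm_volume_ml: float
    flow_rate_ml_s: float
    group: ProtocolGroup
    injection_delay_s: float = 10.0
    saline_flush_ml: float = 25.0

    def __post_init__(self) -> None:
        if not self.cm_volume_ml > 0:
            raise DesignValidationError(
                f"{self.protocol_id}: cm_volume_ml must be > 0"
            )
        if not self.flow_rate_ml_s > 0:
            raise DesignValidationError(
                f"{self.protocol_id}: flow_rate_ml_s must be > 0"
            )
        if self.injection_delay_s < 0 or self.saline_flush_ml < 0:
            raise DesignValidationError(
                f"{self.protocol_id}: delay and flush must be >= 0"
            )


@dataclass(frozen=True)
class InjectorConfig:
    injector_id: str
    pump_type: PumpType
    line_volume_ml: float
    max_pressure: float
    line_config: LineConfig = LineConfig.REGULAR

    def __post_init__(self) -> None:
        if not self.line_volume_ml > 0:
            raise DesignValidationError(
                f"{self.injector_id}: line_volume_ml must be > 0"
            )
        if not self.max_pressure > 0:
            raise DesignValidationError(
                f"{self.injector_id}: max_pressure must be > 0"
            )


@dataclass
class TCRecording:
    """One photometric time-contrast recording plus acquisition metadata."""

    recording_id: str
    time_s: np.ndarray
    signal: np.ndarray
    sampling_hz: float = DEFAULT_SAMPLING_HZ
    injector_id: str = ""
    protocol_id: str = ""
    day: int = 1
    cm_type: CMType | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_s.ndim != 1 or self.signal.ndim != 1:
            raise RecordingParseError("time and signal must be 1-D")
        if len(self.time_s) != len(self.signal):
            raise RecordingParseError(
                f"{self.recording_id}: time ({len(self.time_s)}) and signal "
                f"({len(self.signal)}) lengths differ"
            )
        if len(self.time_s) < 2:
            raise RecordingParseError(
                f"{self.recording_id}: need at least 2 samples"
            )
        if not np.all(np.diff(self.time_s) > 0):
            raise RecordingParseError(
                f"{self.recording_id}: time must be strictly increasing"
            )
        if not self.sampling_hz > 0:
            raise RecordingParseError("sampling_hz must be > 0")
        # Flag (do not reject) recordings whose sample spacing disagrees
        # with the nominal rate by more than 10%.
        med_dt = float(np.median(np.diff(self.time_s)))
        if abs(med_dt - 1.0 / self.sampling_hz) > 0.1 / self.sampling_hz:
            if "irregular_sampling" not in self.flags:
                self.flags.append("irregular_sampling")

    @property
    def n_samples(self) -> int:
        return len(self.time_s)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])


@dataclass(frozen=True)
class StudyDesign:
    injectors: tuple[InjectorConfig, ...]
    protocols: tuple[InjectionProtocol, ...]
    days: int = 2

    def __post_init__(self) -> None:
        if len(self.injectors) == 0:
            raise DesignValidationError("design needs at least one injector")
        if len(self.protocols) == 0:
            raise DesignValidationError("design needs at least one protocol")
        if self.days < 1:
            raise DesignValidationError("days must be >= 1")
        inj_ids = [i.injector_id for i in self.injectors]
        if len(set(inj_ids)) != len(inj_ids):
            raise DesignValidationError("duplicate injector_id in design")
        prot_ids = [p.protocol_id for p in self.protocols]
        if len(set(prot_ids)) != len(prot_ids):
            raise DesignValidationError("duplicate protocol_id in design")

    def injector(self, injector_id: str) -> InjectorConfig:
        for inj in self.injectors:
            if inj.injector_id == injector_id:
                return inj
        raise KeyError(injector_id)

    def protocol(self, protocol_id: str) -> InjectionProtocol:
        for prot in self.protocols:
            if prot.protocol_id == protocol_id:
                return prot
        raise KeyError(protocol_id)


def expected_injection_time(protocol: InjectionProtocol) -> float:
    """Nominal bolus injection time in seconds: volume / flow rate."""
    return protocol.cm_volume_ml / protocol.flow_rate_ml_s


def protocol_in_group(
    protocol: InjectionProtocol, group: ProtocolGroup | str
) -> bool:
    """Protocol-group membership used for sub-group analyses.

    The 10 ml at 5 ml/s protocols sit on the overlap of the variable-volume
    and constant-volume grids and count as members of both groups, even
    though each protocol carries a single primary ``group`` label.
    """
    group = ProtocolGroup(group)
    if protocol.group == group:
        return True
    overlap = (
        abs(protocol.cm_volume_ml - 10.0) < 1e-9
        and abs(protocol.flow_rate_ml_s - 5.0) < 1e-9
    )
    return overlap and group in (ProtocolGroup.VVOL, ProtocolGroup.CVOL)


# ---------------------------------------------------------------------------
# Recording CSV I/O


def read_recording(
    path: str | Path, metadata: Mapping[str, object] | None = None
) -> TCRecording:
    """Read a two-column (time_s, signal) CSV into a :class:`TCRecording`.

    Commas separate fields, '.' is the decimal mark, and a single header
    line is auto-detected and skipped.  ``metadata`` supplies acquisition
    context (injector_id, protocol_id, day, cm_type, sampling_hz,
    recording_id); unknown keys are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    metadata = dict(metadata or {})
    times: list[float] = []
    signals: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 2:
                raise RecordingParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            try:
                t, s = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1 and not times:
                    continue  # header line
                raise RecordingParseError(
                    f"{path}:{lineno}: non-numeric row {parts!r}"
                ) from None
            times.append(t)
            signals.append(s)
    if len(times) < 2:
        raise RecordingParseError(f"{path}: fewer than 2 data rows")
    allowed = {
        "recording_id",
        "sampling_hz",
        "injector_id",
        "protocol_id",
        "day",
        "cm_type",
    }
    unknown = set(metadata) - allowed
    if unknown:
        raise RecordingParseError(f"unknown metadata keys: {sorted(unknown)}")
    if "cm_type" in metadata and metadata["cm_type"] is not None:
        metadata["cm_type"] = CMType(str(metadata["cm_type"]).lower())
    metadata.setdefault("recording_id", path.stem)
    return TCRecording(
        time_s=np.array(times), signal=np.array(signals), **metadata
    )


def write_recording(rec: TCRecording, path: str | Path) -> Path:
    """Write a recording as a 2-column CSV with header, round-trip exact."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("time_s,signal\n")
        for t, s in zip(rec.time_s, rec.signal):
            fh.write(f"{float(t)!r},{float(s)!r}\n")
    return path


# ---------------------------------------------------------------------------
# Study design


def _build_protocol(entry: Mapping[str, object]) -> InjectionProtocol:
    try:
        return InjectionProtocol(
            protocol_id=str(entry["protocol_id"]),
            cm_type=CMType(str(entry["cm_type"]).lower()),
            cm_volume_ml=float(entry["cm_volume_ml"]),
            flow_rate_ml_s=float(entry["flow_rate_ml_s"]),
            group=ProtocolGroup(str(entry["group"])),
            injection_delay_s=float(entry.get("injection_delay_s", 10.0)),
            saline_flush_ml=float(entry.get("saline_flush_ml", 25.0)),
        )
    except KeyError as exc:
        raise DesignValidationError(
            f"protocol entry missing required field {exc}"
        ) from None
    except ValueError as exc:
        raise DesignValidationError(f"bad protocol entry: {exc}") from None


def _build_injector(entry: Mapping[str, object]) -> InjectorConfig:
    try:
        return InjectorConfig(
            injector_id=str(entry["injector_id"]),
            pump_type=PumpType(str(entry["pump_type"])),
            line_volume_ml=float(entry["line_volume_ml"]),
            max_pressure=float(entry["max_pressure"]),
            line_config=LineConfig(str(entry.get("line_config", "regular"))),
        )
    except KeyError as exc:
        raise DesignValidationError(
            f"injector entry missing required field {exc}"
        ) from None
    except ValueError as exc:
        raise DesignValidationError(f"bad injector entry: {exc}") from None


def read_study_design(path: str | Path) -> StudyDesign:
    """Read a YAML study design (see ``designs/default_design.yaml``)."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise DesignValidationError(f"{path}: design must be a mapping")
    injectors = tuple(_build_injector(e) for e in doc.get("injectors") or [])
    protocols = tuple(_build_protocol(e) for e in doc.get("protocols") or [])
    return StudyDesign(
        injectors=injectors,
        protocols=protocols,
        days=int(doc.get("days", 2)),
    )


def default_design(experimental: bool = False) -> StudyDesign:
    """The bundled bench-study design: five injector models, 14 protocols.

    With ``experimental=True`` the two line-swap configurations (the
    lowest-power PS model fitted with the large RP tube line and vice
    versa) are included as additional injector configurations, which is
    what the covariate analysis needs to separate line volume from pump
    type.
    """
    from importlib import resources

    with resources.as_file(
        resources.files("bolusqc") / "designs" / "default_design.yaml"
    ) as p:
        design = read_study_design(p)
    if experimental:
        return design
    regular = tuple(
        i for i in design.injectors if i.line_config is LineConfig.REGULAR
    )
    return StudyDesign(
        injectors=regular, protocols=design.protocols, days=design.days
    )


def stable_seed(*parts: object) -> int:
    """Deterministic sub-2**31 seed derived from a hash of its arguments."""
    digest = hashlib.sha256(":".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
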