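"""Event-level cytometry data: containers, CSV interchange, arcsinh transform, downsampling.

The pipeline operates on per-sample event tables (cells x fluorescence channels).
Channels carry roles: seven *lineage* channels drive clustering, five *inhibitory
receptor* (IR) channels drive gating and signatures, and a viability channel is
used only for pre-gating. Fluorescence is analysed on the arcsinh scale
``asinh(x / cofactor)``, the standard variance-stabilizing transform for
cytometry; the cofactor sets where the linear-to-log transition happens.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LINEAGE_CHANNELS: tuple[str, ...] = ("CD3", "CD4", "CD8", "gdTCR", "CD127", "CD16", "CD56")
IR_CHANNELS: tuple[str, ...] = ("PD-1", "TIGIT", "TIM-3", "CD160", "LAG-3")
VIABILITY_CHANNEL = "Viability"

#: conventional fluorescence-cytometry arcsinh scale; exposed, not hidden
DEFAULT_COFACTOR = 150.0

CHANNEL_ROLES = ("lineage", "ir", "viability", "dump", "other")


class EventsError(ValueError):
    """Raised for malformed event matrices or misuse of transforms."""


def default_channel_roles() -> dict[str, str]:
    roles = {c: "lineage" for c in LINEAGE_CHANNELS}
    roles.update({c: "ir" for c in IR_CHANNELS})
    roles[VIABILITY_CHANNEL] = "viability"
    return roles


@dataclasses.dataclass
class EventMatrix:
    """One sample's per-cell fluorescence values.

    Parameters
    ----------
    sample_id
        Subject or control identifier.
    values
        events x channels table; column names are channel names.
    channel_roles
        Mapping channel -> one of :data:`CHANNEL_ROLES`; must cover every column.
    transform_state
        ``"raw"`` (instrument units) or ``"arcsinh"`` (dimensionless).
    cofactor
        arcsinh scale c used (or to be used) for this sample.
    meta
        Optional per-event metadata aligned with ``values`` (e.g. the synthetic
        generator's hidden cell-subset labels). Never used by the analysis.
    warn_empty
        Set when a gating step produced zero events.
    """

    sample_id: str
    values: pd.DataFrame
    channel_roles: Mapping[str, str]
    transform_state: str = "raw"
    cofactor: float = DEFAULT_COFACTOR
    meta: pd.DataFrame | None = None
    warn_empty: bool = False

    def __post_init__(self) -> None:
        if self.transform_state not in ("raw", "arcsinh"):
            raise EventsError(f"unknown transform_state {self.transform_state!r}")
        if not self.cofactor > 0:
            raise EventsError("cofactor must be > 0")
        cols = list(self.values.columns)
        if len(set(cols)) != len(cols):
            raise EventsError("channel names must be unique")
        unmapped = [c for c in cols if c not in self.channel_roles]
        if unmapped:
            raise EventsError(f"channels lacking a role mapping: {unmapped}")
        bad = {c: r for c, r in self.channel_roles.items() if r not in CHANNEL_ROLES}
        if bad:
            raise EventsError(f"unknown channel roles: {bad}")
        if self.values.isna().any().any():
            raise EventsError("event matrix contains missing values")
        if self.meta is not None and len(self.meta) != len(self.values):
            raise EventsError("meta must align with values row-for-row")

    @property
    def n_events(self) -> int:
        return len(self.values)

    @property
    def channels(self) -> list[str]:
        return list(self.values.columns)

    def channels_with_role(self, role: str) -> list[str]:
        return [c for c in self.values.columns if self.channel_roles.get(c) == role]

    def channel(self, name: str) -> np.ndarray:
        return self.values[name].to_numpy()

    def take(self, index: np.ndarray, warn_empty: bool = False) -> "EventMatrix":
        """Row subset preserving order, roles and transform state."""
        return EventMatrix(
            sample_id=self.sample_id,
            values=self.values.iloc[index].reset_index(drop=True),
            channel_roles=dict(self.channel_roles),
            transform_state=self.transform_state,
            cofactor=self.cofactor,
            meta=None if self.meta is None else self.meta.iloc[index].reset_index(drop=True),
            warn_empty=warn_empty,
        )


def read_events(
    path: str | Path,
    format: str = "csv",
    channel_roles: Mapping[str, str] | None = None,
    sample_id: str | None = None,
) -> EventMatrix:
    """Read a per-sample event table.

    CSV is the canonical interchange dialect: comma-separated, header row of
    channel names, UTF-8, no index column. Values read from disk are treated as
    raw instrument units (``transform_state="raw"``) unless the caller
    re-labels them. FCS input is not supported in this build; export events as
    CSV instead.
    """
    path = Path(path)
    if format == "fcs":
        raise NotImplementedError(
            "FCS input is not supported; export events as CSV (header = channel names)"
        )
    if format != "csv":
        raise EventsError(f"unknown format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    values = pd.read_csv(path)
    roles = dict(channel_roles) if channel_roles is not None else default_channel_roles()
    unmapped = [c for c in values.columns if c not in roles]
    if unmapped:
        raise EventsError(f"channels lacking a role mapping: {unmapped}")
    return EventMatrix(
        sample_id=sample_id or path.stem,
        values=values,
        channel_roles=roles,
        transform_state="raw",
    )


def write_events(m: EventMatrix, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    m.values.to_csv(path, index=False)


def arcsinh_transform(m: EventMatrix, cofactor: float | None = None) -> EventMatrix:
    """Apply x -> asinh(x / cofactor) to every channel.

    Monotone and invertible; guarded against double application.
    """
    if m.transform_state == "arcsinh":
        raise EventsError("event matrix is already arcsinh-transformed")
    c = float(cofactor if cofactor is not None else m.cofactor)
    if not c > 0:
        raise EventsError("cofactor must be > 0")
    values = pd.DataFrame(
        np.arcsinh(m.values.to_numpy(dtype=float) / c),
        columns=m.values.columns,
    )
    return EventMatrix(m.sample_id, values, dict(m.channel_roles), "arcsinh", c, m.meta)


def inverse_arcsinh_transform(m: EventMatrix) -> EventMatrix:
    """Recover raw values: x = sinh(y) * cofactor."""
    if m.transform_state != "arcsinh":
        raise EventsError("event matrix is not arcsinh-transformed")
    values = pd.DataFrame(
        np.sinh(m.values.to_numpy(dtype=float)) * m.cofactor,
        columns=m.values.columns,
    )
    return EventMatrix(m.sample_id, values, dict(m.channel_roles), "raw", m.cofactor, m.meta)


def downsample(m: EventMatrix, n: int, seed: int | np.random.Generator = 0) -> EventMatrix:
    """Uniform sample of ``min(n, n_events)`` rows without replacement.

    Row order of the retained events is preserved (sorted selection), so the
    result is stable under a fixed seed.
    """
    if n < 0:
        raise EventsError("n must be >= 0")
    if n >= m.n_events:
        if n > m.n_events:
            logger.info("downsample: requested %d > %d events in %s; keeping all",
                        n, m.n_events, m.sample_id)
        return m.take(np.arange(m.n_events))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = np.sort(rng.choice(m.n_events, size=n, replace=False))
    return m.take(idx)


def check_compatible(samples: Iterable[EventMatrix]) -> None:
    """Require shared channels, transform state and cofactor before pooling."""
    samples = list(samples)
    if not samples:
        raise EventsError("no samples")
    ref = samples[0]
    for s in samples[1:]:
        if s.channels != ref.channels:
            raise EventsError(f"channel mismatch between {ref.sample_id} and {s.sample_id}")
        if s.transform_state != ref.transform_state:
            raise EventsError("transform_state differs across samples")
        if s.cofactor != ref.cofactor:
            raise EventsError("cofactor differs across samples")
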