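"""Minimal European Data Format (EDF) writer.

Writes continuous multichannel data as standard EDF: ASCII header blocks of
256 bytes (one global, one per signal) followed by little-endian 16-bit data
records. All channels share one sampling rate; physical units are µV. The
record duration is chosen so the signal length divides into whole records
(falling back to zero-padding the final record). Reading is delegated to MNE
elsewhere; this module exists only because the interchange format is EDF.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

_RECORD_DURATIONS = (1.0, 0.5, 0.2, 0.1, 0.05, 0.02, 0.01)
_DIG_MAX = 32767


def _ascii_field(value: str, width: int) -> bytes:
    out = value.encode("ascii")
    if len(out) > width:
        raise ValueError(f"EDF field {value!r} exceeds {width} bytes")
    return out.ljust(width)


def _num_field(value: float, width: int = 8) -> bytes:
    for fmt in ("%g", "%.5g", "%.4g", "%.3g"):
        s = fmt % value
        if len(s) <= width:
            return _ascii_field(s, width)
    raise ValueError(f"cannot format {value} in {width} ASCII bytes")


def _pick_record_duration(n_samples: int, fs: float) -> tuple[float, int]:
    for dur in _RECORD_DURATIONS:
        spr = dur * fs
        if abs(spr - round(spr)) < 1e-9 and n_samples % round(spr) == 0:
            return dur, int(round(spr))
    # no clean divisor: pad to whole 1 s records
    return 1.0, int(round(fs))


def write_edf(
    path: Path,
    samples: np.ndarray,
    sampling_rate: float,
    labels: list[str],
    physical_dimension: str = "uV",
) -> None:
    """Write ``samples`` (channels x time, physical units) as 16-bit EDF."""
    samples = np.asarray(samples, dtype=float)
    n_channels, n_samples = samples.shape
    if len(labels) != n_channels:
        raise ValueError("one label per channel required")

    record_dur, spr = _pick_record_duration(n_samples, sampling_rate)
    n_records = -(-n_samples // spr)
    padded = n_records * spr
    if padded != n_samples:
        logger.warning(
            "EDF record length %d does not divide %d samples; zero-padding "
            "final record",
            spr,
            n_samples,
        )
        samples = np.pad(samples, ((0, 0), (0, padded - n_samples)))

    # Per-channel physical range. Quantization uses the values exactly as
    # written to the header so the reader reconstructs with the same scale.
    phys_max_strs, scales = [], []
    for ch in range(n_channels):
        amp = float(np.max(np.abs(samples[ch])))
        amp = amp * 1.0005 if amp > 0 else 1.0
        field = _num_field(amp)
        phys_max_strs.append(field)
        scales.append(float(field.decode().strip()))

    header = bytearray()
    header += _ascii_field("0", 8)
    header += _ascii_field("X X X X", 80)
    header += _ascii_field("Startdate X X X X", 80)
    header += _ascii_field("01.01.01", 8)
    header += _ascii_field("00.00.00", 8)
    header += _num_field(256 * (n_channels + 1))
    header += _ascii_field("", 44)
    header += _num_field(n_records)
    header += _num_field(record_dur)
    header += _num_field(n_channels, 4)

    def signal_block(width: int, values: list[bytes]) -> bytes:
        return b"".join(v if isinstance(v, bytes) else _ascii_field(v, width) for v in values)

    header += b"".join(_ascii_field(lab, 16) for lab in labels)
    header += b"".join(_ascii_field("", 80) for _ in range(n_channels))
    header += b"".join(_ascii_field(physical_dimension, 8) for _ in range(n_channels))
    header += b"".join(_num_field(-s) for s in scales)
    header += signal_block(8, phys_max_strs)
    header += b"".join(_num_field(-_DIG_MAX) for _ in range(n_channels))
    header += b"".join(_num_field(_DIG_MAX) for _ in range(n_channels))
    header += b"".join(_ascii_field("", 80) for _ in range(n_channels))
    header += b"".join(_num_field(spr) for _ in range(n_channels))
    header += b"".join(_ascii_field("", 32) for _ in range(n_channels))

    digital = np.empty_like(samples, dtype="<i2")
    for ch in range(n_channels):
        digital[ch] = np.clip(
            np.rint(samples[ch] / scales[ch] * _DIG_MAX), -_DIG_MAX, _DIG_MAX
        ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for rec in range(n_records):
            chunk = digital[:, rec * spr : (rec + 1) * spr]
            fh.write(chunk.tobytes())
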