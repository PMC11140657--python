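"""Test-support utilities: minimal writers for tiny EDF and BrainVision
fixtures (generated at test time; the environment ships readers but no
writers for these formats)."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def write_edf(path: Path, data: np.ndarray, fs: float, labels: list[str],
              phys_dim: str = "uV") -> None:
    """Write a minimal EDF file (one data record spanning the whole signal).

    ``data`` is channels x samples in the units named by ``phys_dim``.
    """
    n_ch, n_samp = data.shape
    rec_dur = n_samp / fs
    phys_min = float(np.floor(data.min() - 1))
    phys_max = float(np.ceil(data.max() + 1))
    dig_min, dig_max = -32768, 32767

    def f(x: object, n: int) -> bytes:
        s = str(x)[:n]
        return s.ljust(n).encode("ascii")

    hdr = b"".join([
        f("0", 8), f("synthetic", 80), f("synthetic", 80),
        f("01.01.20", 8), f("00.00.00", 8),
        f(256 + 256 * n_ch, 8), f("", 44), f(1, 8),
        f(f"{rec_dur:g}", 8), f(n_ch, 4),
    ])
    sig = b"".join([
        b"".join(f(lab, 16) for lab in labels),
        b"".join(f("synthetic", 80) for _ in labels),
        b"".join(f(phys_dim, 8) for _ in labels),
        b"".join(f(f"{phys_min:g}", 8) for _ in labels),
        b"".join(f(f"{phys_max:g}", 8) for _ in labels),
        b"".join(f(dig_min, 8) for _ in labels),
        b"".join(f(dig_max, 8) for _ in labels),
        b"".join(f("", 80) for _ in labels),
        b"".join(f(n_samp, 8) for _ in labels),
        b"".join(f("", 32) for _ in labels),
    ])
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    dig = np.round((data - phys_min) * scale + dig_min).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr + sig)
        fh.write(dig.tobytes())  # record-major: ch1 samples, ch2 samples, ...


def write_brainvision(stem: Path, data: np.ndarray, fs: float,
                      labels: list[str], with_eeg: bool = True) -> Path:
    """Write a minimal BrainVision triplet; returns the .vhdr path."""
    vhdr = stem.with_suffix(".vhdr")
    vmrk = stem.with_suffix(".vmrk")
    eeg = stem.with_suffix(".eeg")
    n_ch = data.shape[0]
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={1e6 / fs:g}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    for i, lab in enumerate(labels, 1):
        lines.append(f"Ch{i}={lab},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")
    vmrk.write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n"
        "[Common Infos]\n"
        f"DataFile={eeg.name}\n"
        "[Marker Infos]\n"
        "Mk1=New Segment,,1,1,0,00000000000000000000\n",
        encoding="utf-8",
    )
    if with_eeg:
        eeg.write_bytes(np.asarray(data, dtype="<f4").T.tobytes())
    return vhdr
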