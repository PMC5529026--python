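"""TSV read/write with `#`-prefixed provenance header comments."""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

__all__ = ["write_tsv", "read_tsv", "sha256_file", "derive_seed"]


def write_tsv(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> Path:
    """Write a table as TSV with one `# key: value` comment line per meta item."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage sub-seed (< 2^31) from the run seed and stage name."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
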