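"""Run manifests and CSV report writing shared by the CLI stages."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__

__all__ = ["RunManifest", "write_table", "write_manifest"]


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance of one CLI run; identical manifests (minus timestamp)
    guarantee byte-identical numeric outputs."""

    command: str
    config_path: str
    config_sha256: str
    seed: int | None
    n_draws: int | None
    options: dict = field(default_factory=dict)
    version: str = __version__
    timestamp: str = ""

    @classmethod
    def create(
        cls,
        command: str,
        config_path: str | Path,
        seed: int | None,
        n_draws: int | None,
        **options,
    ) -> "RunManifest":
        return cls(
            command=command,
            config_path=str(config_path),
            config_sha256=_sha256(config_path),
            seed=seed,
            n_draws=n_draws,
            options=options,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )


def write_table(df: pd.DataFrame, path: str | Path, round_dollars: bool = False) -> Path:
    """Write a result table as CSV with a stable float format.

    ``round_dollars`` renders dollar-valued columns to whole dollars for
    report style; internal arithmetic is never rounded.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    if round_dollars:
        for col in out.columns:
            if out[col].dtype.kind == "f" and ("cost" in col or "benefit" in col or col in {"icer", "enbs", "trial_cost"}):
                out[col] = out[col].round(0)
    out.to_csv(path, index=False, float_format="%.10g")
    return path


def write_manifest(manifest: RunManifest, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{manifest.command}_manifest.json"
    with open(path, "w") as fh:
        json.dump(asdict(manifest), fh, indent=2)
        fh.write("\n")
    return path
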