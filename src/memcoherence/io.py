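"""Reading and writing the ResponseTable CSV dialect and run configuration.

The dialect is a plain comma-separated UTF-8 file with header
``participant_id,condition,encoding_order,event_id,cue_category,
target_category,correct`` and 0/1 correctness. ``column_map`` lets
differently named exports (e.g. re-analyses of deposited data) be read
without rewriting the file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .behavior import GeneratorSpec
from .dependency import REQUIRED_COLS, validate_response_table
from .network import ModelParams

__all__ = [
    "read_response_table",
    "write_response_table",
    "RunConfig",
    "load_config",
    "dump_config",
]


def read_response_table(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Load and validate a ResponseTable CSV.

    ``column_map`` maps file column names to dialect names.
    """
    df = pd.read_csv(path, comment="#")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[REQUIRED_COLS].copy()
    if not pd.api.types.is_integer_dtype(df["correct"]):
        raise ValueError(f"{path}: 'correct' must be integer 0/1")
    validate_response_table(df)
    return df


def write_response_table(rt: pd.DataFrame, path, header_comment: str | None = None) -> None:
    validate_response_table(rt)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        rt[REQUIRED_COLS].to_csv(fh, index=False)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; round-trips through YAML."""

    seed: int = 0
    n_neutral: int = 36
    n_negative: int = 36
    mode: str = "pairs"  # "pairs" | "triples"
    p_g: float = 1.0
    n_choices: int = 6
    model: ModelParams = field(default_factory=ModelParams)
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)
    out_dir: str = "results"


def dump_config(cfg: RunConfig, path) -> None:
    payload = {
        "seed": cfg.seed,
        "n_neutral": cfg.n_neutral,
        "n_negative": cfg.n_negative,
        "mode": cfg.mode,
        "p_g": cfg.p_g,
        "n_choices": cfg.n_choices,
        "model": asdict(cfg.model),
        "generator": asdict(cfg.generator),
        "out_dir": cfg.out_dir,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh) or {}
    model = ModelParams(**payload.pop("model", {}))
    gen = payload.pop("generator", {})
    for key in ("conditions", "orders"):
        if key in gen:
            gen[key] = tuple(gen[key])
    generator = GeneratorSpec(**gen)
    return RunConfig(model=model, generator=generator, **payload)
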