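"""On-disk cache for Monte-Carlo engine tables.

Each table is stored as a TSV matrix plus a JSON sidecar recording the
simulation parameters (N, horizon, replicates, seed, effective selection,
grids), keyed by a hash of those parameters so stale tables are never
reused after a configuration change.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .pde import EngineTable

__all__ = ["TableCache"]


class TableCache:
    def __init__(self, directory) -> None:
        self.dir = Path(directory)
        self.dir.mkdir(parents=True, exist_ok=True)

    @staticmethod
    def _hash(key, cfg) -> str:
        payload = json.dumps(
            {
                "key": [list(k) if isinstance(k, tuple) else k for k in key],
                "N": cfg.N,
                "n_gen": cfg.n_gen,
                "reps_fix": cfg.reps_fix,
                "reps_moment": cfg.reps_moment,
                "seed": cfg.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:16]

    def _paths(self, key, cfg) -> tuple[Path, Path]:
        h = self._hash(key, cfg)
        return self.dir / f"{h}.tsv", self.dir / f"{h}.json"

    def load(self, key, cfg) -> EngineTable | None:
        tsv, meta_path = self._paths(key, cfg)
        if not (tsv.exists() and meta_path.exists()):
            return None
        meta = json.loads(meta_path.read_text())
        data = np.loadtxt(tsv, delimiter="\t", ndmin=2)
        nt = len(meta["taus"])
        values = data[:nt]
        se = data[nt:] if data.shape[0] > nt else None
        return EngineTable(
            y=np.asarray(meta["y"]),
            taus=np.asarray(meta["taus"]),
            values=values,
            gamma_eff=meta["gamma_eff"],
            f_at_0=meta["f_at_0"],
            f_at_1=meta["f_at_1"],
            se=se,
        )

    def store(self, key, cfg, table: EngineTable) -> None:
        tsv, meta_path = self._paths(key, cfg)
        meta = {
            "y": table.y.tolist(),
            "taus": table.taus.tolist(),
            "gamma_eff": table.gamma_eff,
            "f_at_0": table.f_at_0,
            "f_at_1": table.f_at_1,
            "N": cfg.N,
            "n_gen": cfg.n_gen,
            "reps_fix": cfg.reps_fix,
            "reps_moment": cfg.reps_moment,
            "seed": cfg.seed,
        }
        meta_path.write_text(json.dumps(meta))
        data = table.values if table.se is None else np.vstack([table.values, table.se])
        np.savetxt(tsv, data, delimiter="\t")

    def clear(self) -> None:
        for p in self.dir.glob("*.tsv"):
            p.unlink()
        for p in self.dir.glob("*.json"):
            p.unlink()
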