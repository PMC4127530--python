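"""Search-control parameters shared by the MP and ML engines."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

__all__ = ["SearchParams"]


@dataclass
class SearchParams:
    """Heuristic-search settings.

    MP defaults follow the classical recipe: 100 rounds of random sequence
    addition with TBR swapping, keeping at most 10 best trees per round and
    collapsing zero-length branches; MP bootstraps use 1000 replicates with
    10 addition rounds each.  ML uses fast bootstrapping (one addition
    start plus NNI per replicate) and the autoMRE bootstopping rule: stop
    when, at a 50-replicate checkpoint, the mean weighted Robinson–Foulds
    distance between majority-rule consensus trees of 100 random half
    splits drops below 0.03.
    """

    addition_rounds: int = 100
    swap: str = "tbr"                  # tbr | nni | none
    max_trees_per_round: int = 10
    collapse_zero_length: bool = True
    bootstrap_replicates: int = 1000
    bootstrap_rounds: int = 10
    fast_bootstrap: bool = True
    automre_threshold: float = 0.03
    automre_checkpoint: int = 50
    automre_splits: int = 100
    max_bootstrap: int = 1000
    ml_start_rounds: int = 3
    nni_tol: float = 1e-4
    max_nni_rounds: int = 25
    brlen_passes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.addition_rounds, self.bootstrap_replicates,
               self.max_bootstrap) < 1:
            raise ValueError("replicate and round counts must be >= 1")
        if self.swap not in {"tbr", "nni", "none"}:
            raise ValueError("swap must be tbr, nni or none")

    def write_manifest(self, path, **extra) -> None:
        """Echo seed and parameters (plus any run metadata) as JSON."""
        payload = dataclasses.asdict(self)
        payload.update(extra)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)
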