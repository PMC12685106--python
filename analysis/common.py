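"""Shared paths and helpers for the numbered analysis drivers."""

import os
import sys

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
COHORT_DIR = os.path.join(ROOT, "results", "cohort")
OUT_DIR = os.path.join(ROOT, "results", "analysis")
SEED = 1

PLANTED_MZ = (688.4921, 699.5014, 714.5123, 740.5229, 864.5707, 913.5778, 915.5901)


def require(path: str, producer: str) -> str:
    if not os.path.exists(path):
        sys.exit(f"missing {path}; run analysis/{producer} first")
    return path


def ensure_out() -> str:
    os.makedirs(OUT_DIR, exist_ok=True)
    return OUT_DIR
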