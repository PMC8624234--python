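#!/usr/bin/env python
"""Download the case-study structures from the RCSB into tests/data/pdb/.

The library itself never touches the network; this helper exists so the
published case-study checks (T4 lysozyme 2LZM/2O4W, Hsp70 2KHO/4B9Q,
glucocorticoid-receptor LBD 1M2Z) can run on a machine with internet access.

Usage:
    python scripts/fetch_pdb.py [CODE ...]
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

DEFAULT_CODES = ["2lzm", "2o4w", "2kho", "4b9q", "1m2z"]
TARGET_DIR = Path(__file__).resolve().parent.parent / "tests" / "data" / "pdb"


def fetch(code: str) -> Path:
    code = code.lower()
    TARGET_DIR.mkdir(parents=True, exist_ok=True)
    target = TARGET_DIR / f"{code}.pdb"
    if target.exists():
        print(f"{code}: already present at {target}")
        return target
    url = f"https://files.rcsb.org/download/{code.upper()}.pdb"
    print(f"{code}: fetching {url}")
    with urllib.request.urlopen(url, timeout=60) as response:
        target.write_bytes(response.read())
    print(f"{code}: wrote {target} ({target.stat().st_size} bytes)")
    return target


if __name__ == "__main__":
    codes = sys.argv[1:] or DEFAULT_CODES
    for code in codes:
        fetch(code)
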