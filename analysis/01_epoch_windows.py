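#!/usr/bin/env python
"""Derive the shock-locked analysis windows from the session protocol.

The observational-fear-conditioning session is 5 min of habituation followed
by 4 min of conditioning in which a 2-s foot shock recurs every 12 s.  This
driver derives the guard-trimmed analysis windows (1 s dropped at each end of
every inter-shock interval) and the 10-s habituation tiles, and writes the
combined interval table to results/epochs.tsv.
"""

from pathlib import Path

import pandas as pd

from ofcnet.protocol import (
    SessionProtocol,
    conditioning_epochs,
    epochs_clear_of_shocks,
    habituation_epochs,
    quarter_partition,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    protocol = SessionProtocol()
    hab = habituation_epochs(protocol)
    cond = conditioning_epochs(protocol)
    quarters = quarter_partition(protocol, cond)

    assert epochs_clear_of_shocks(protocol, cond)
    table = pd.concat([hab.to_frame(), cond.to_frame()], ignore_index=True)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "epochs.tsv", sep="\t", index=False)

    print(f"habituation: {len(hab)} windows of {hab.window:.0f} s")
    print(f"conditioning: {len(cond)} guard-trimmed windows of {cond.window:.0f} s")
    print(f"quarters: {[len(q) for q in quarters]} windows each")
    print(f"wrote {OUT / 'epochs.tsv'}")


if __name__ == "__main__":
    main()
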