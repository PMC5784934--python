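#!/usr/bin/env python
"""Build the experimental designs and export their schedules.

Constructs the simultaneous-triples design (36 events: one encoding trial
per event, 216 both-direction 6-AFC test trials) and the overlapping-pairs
design (72 events across three encoding blocks under person-last /
person-first orders, 432 test trials), then writes both as CSV under
results/schedules/.
"""

from pathlib import Path

from memcoherence import assign_orders, make_encoding_schedule, make_events, make_test_schedule
from memcoherence.design import encoding_to_frame, test_to_frame

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "schedules"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for label, n_per_cond, mode in [("triples", 18, "triples"), ("pairs", 36, "pairs")]:
        events = make_events(n_per_cond, n_per_cond, SEED)
        orders = assign_orders(events, mode, SEED + 1)
        enc = make_encoding_schedule(events, mode, orders, SEED + 2)
        test = make_test_schedule(events, SEED + 3)
        encoding_to_frame(enc, events).to_csv(OUT / f"{label}_encoding.csv", index=False)
        test_to_frame(test, events, enc.order).to_csv(OUT / f"{label}_test.csv", index=False)
        print(
            f"{label}: {len(events)} events -> {len(enc.trials)} encoding trials "
            f"in {enc.n_blocks} block(s), {len(test.trials)} test trials"
        )


if __name__ == "__main__":
    main()
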