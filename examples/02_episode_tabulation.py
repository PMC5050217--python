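"""Tabulate independent infection episodes with the waiting-list rule.

Three pneumonia records at days 3, 7, and 15: the 4-day gap is inside
the 6-day similar window (same type/mode/pathogen), the 8-day gap is
not, so the patient has two independent episodes.
"""

from burncohort import (InfectionRecord, WaitingListPolicy,
                        classify_hypersusceptible, tabulate_episodes)

records = [
    InfectionRecord("p1", day, "pneumonia", "nosocomial", "s. aureus")
    for day in (3.0, 7.0, 15.0)
]
tally = tabulate_episodes(records, WaitingListPolicy())
print(f"n_episodes = {tally.n_episodes}")
print(f"record -> episode assignment: {tally.assignment}")
print(f"hypersusceptible (>=3 episodes): {classify_hypersusceptible(tally)}")

# A dissimilar record only waits 2 days, but each joining record re-arms
# its episode's window:
mixed = [
    InfectionRecord("p2", 3.0, "pneumonia", "nosocomial", "s. aureus"),
    InfectionRecord("p2", 4.0, "uti", "nosocomial", "e. coli"),
    InfectionRecord("p2", 8.0, "uti", "nosocomial", "e. coli"),
]
print(f"mixed history -> {tabulate_episodes(mixed).n_episodes} episode(s)")
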