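"""Transcription audit of the packaged parameter tables.

Recounts each table's valid groups (molecule support >= 3, non-blank
contribution) and reports the result against the printed row A value.
Discrepancies are surfaced as data notes, never reconciled.
"""

import json

from thermogroups import load_all_tables

for d, table in load_all_tables().items():
    print(json.dumps(table.audit(), indent=2))
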