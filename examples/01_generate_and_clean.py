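"""Generate a synthetic FAERS-like database, write quarterly files, and run
the cleaning chain: quarter merge -> deletion purge -> deduplication ->
case-level join -> target-drug selection."""

import tempfile
from pathlib import Path

import pvsignal as pv
from pvsignal import faers_io
from pvsignal.synthetic import TARGET_SEARCH_NAMES, scenario_reference_cohort, write_files

out = Path(tempfile.mkdtemp(prefix="pvsignal_demo_"))
synth = scenario_reference_cohort(seed=1)
files = write_files(synth, out)
print(f"wrote {len(files)} quarterly files to {out}")

ds, deleted = faers_io.load_directory(out)
print(f"raw: {len(ds.cases)} report versions, {len(deleted)} case ids on deletion lists")

clean = pv.clean_dataset(ds, deleted)
report = faers_io.validate_counts(clean, {"cases": len(clean.cases)})
print(f"clean: {len(clean.cases)} unique cases (validation ok={report['ok']})")

target = faers_io.filter_target_drug(clean, TARGET_SEARCH_NAMES, role="PS")
flat = pv.join_case_level(target)
print(f"target drug: {len(target.cases)} cases, "
      f"{flat['pt'].notna().sum()} coded reaction rows")
# The deduplicated target cohort is what every downstream stage consumes;
# the validation report flags any count drift against an expected figure.
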