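# The FAERS ASCII dialect accepted by `pvsignal.faers_io`

Quarterly extract files are plain text, one record per line, fields
separated by a literal `$` with no quoting.  The first line is a header of
lower- or upper-case column names.  One file per entity per quarter, named
`<kind>_<year>q<quarter>.txt` (e.g. `demo_2021q3.txt`); deletion lists are
`deleted_<year>q<quarter>.txt` with the single column `caseid`.

## Required columns

| kind    | columns                                                               |
|---------|-----------------------------------------------------------------------|
| demo    | primaryid, caseid, caseversion, fda_dt, age, age_cod, sex, occp_cod, occr_country |
| drug    | primaryid, caseid, drug_seq, role_cod, drugname                       |
| reac    | primaryid, caseid, pt  (optional: event_dt)                           |
| ther    | primaryid, caseid, dsg_drug_seq, start_dt                             |
| deleted | caseid                                                                |

Extra columns are ignored.  A missing required column is a schema error
naming the column; an empty file parses to an empty table with a warning.

## Conventions

- **Dates** are `YYYYMMDD`.  Partial dates are padded to the first
  day/month (`2021` -> 2021-01-01, `202104` -> 2021-04-01); anything else
  becomes missing, never an error.
- **Ages** come with a unit code (`YR`, `DEC`, `MON`, `WK`, `DY`, `HR`)
  and are converted to years; a blank code with a numeric age is read as
  years, an unknown code or an age outside [0, 130] years becomes missing.
- **Sex** `M`/`F`; anything else is "unknown".  **Reporter occupation**
  codes `MD`, `HP`, `PH`, `CN`, `OT`/`LW` map to physician, health
  professional, pharmacist, consumer, other; blank is missing.
- **Drug roles** are `PS`/`SS`/`C`/`I` (primary suspect, secondary
  suspect, concomitant, interacting); unknown codes become missing with a
  warning.
- **`event_dt` on reaction rows is a dialect extension**: the public FAERS
  REAC files do not carry per-reaction onset dates.  The time-to-onset
  stage needs an event date per (case, PT) record, so this dialect allows
  one there; files without it still parse, with the event date missing.

## PT-to-SOC map

A two-column tab-separated file with header `pt<TAB>soc`, one system organ
class per preferred term (a simplified stand-in for a licensed MedDRA
hierarchy).  Duplicate identical rows are tolerated; one PT mapped to two
different SOCs is an error.
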