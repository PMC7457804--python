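# File formats

All files are plain text. Ages are integers (completed age, age last
birthday), years are calendar years, and every age interval is
half-open [x, x+1).

## Mortality surfaces

### `Mx_1x1` rate files (read-only, `read_hmd_mx`)

The standard national-statistics layout: free-text header lines, then a
whitespace-separated table

    Year  Age  Female  Male  Total

Age `110+` denotes the open age group; `.` denotes a missing rate.
One sex column is read per call. Ages at and above the configured
terminal age ω are folded into ω (the terminal rate is the rate
reported at age ω); `.` cells become missing markers that raise
`MissingDataError` when a computation needs them. Malformed lines
raise `ParseError` with the line number.

### Long-form surface CSV (read/write, native interchange)

    year,age,rate

One row per Lexis cell; the grid must be complete and rectangular.
Written with `%.12g` floats so a write/read round-trip reproduces the
surface to full precision.

## Prevalence

### Survey microdata CSV (`read_survey_csv`)

    age,year,unhealthy,weight

One row per respondent; `unhealthy` is 0/1, `weight` a positive
sampling weight. One `SurveySample` is produced per year.

### Tabulated counts CSV (`read_tabulated_csv`, CLI input)

    age,year,n_unhealthy,n_total

Counts may be non-integer (weighted). Cells absent from the file are
treated as zero-total (missing) ages.

### Smoothed output CSV (`write_prevalence_csv`, CLI `smooth` output)

    age,year,pi_raw,pi_smooth,n

`pi_raw` is the observed weighted proportion (empty where no
respondents), `pi_smooth` the fitted single-age schedule, `n` the
unweighted respondent count used for standard errors.

## Results

### HealthSummary records (CSV and JSON)

Flat records with columns/keys

    population, year, sex, le, he, cal, hcal,
    ratio_he_le, ratio_hcal_cal,
    he_se, he_lo95, he_hi95, hcal_se, hcal_lo95, hcal_hi95

SE/interval fields are present only when per-age sample sizes were
available. The JSON form is a list of such objects and round-trips
through `read_summaries_json`.

### Comparison records (CLI `compare` output, JSON)

    mode, population, a{year,sex}, b{year,sex},
    d_le, d_he, d_cal, d_hcal, d_ratio_he_le_pp, d_ratio_hcal_cal_pp

Signed a − b; level differences in years, ratio differences in
percentage points.

### `run.yaml`

Every CLI run writes the resolved configuration (defaults < config
file < flags), the seed and the package version next to its outputs;
identical configuration and seed reproduce identical output bytes.

### Life table CSV (CLI `lifetable` output)

    age,mx,qx,ax,lx,dx,Lx,Tx,ex

### Cohort survivorship CSV (CLI `cal` output)

    age,birth_cohort,p_c,L_c
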