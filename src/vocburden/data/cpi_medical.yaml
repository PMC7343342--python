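# Inflation multipliers restating service-year US dollars in 2013 US
# dollars, derived from annual averages of the medical-care component of
# the Consumer Price Index (BLS series CUUR0000SAM): multiplier(y) =
# CPI-Medical(2013) / CPI-Medical(y).  Replace with updated factors to
# change the reference year.
version: 1
reference_year: 2013
factors:
  2009: 1.1318
  2010: 1.0945
  2011: 1.0622
  2012: 1.0246
  2013: 1.0
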