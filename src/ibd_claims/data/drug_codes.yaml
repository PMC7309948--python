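# Default biologic identification code maps.
#
# These are documented defaults, not a transcription of any payer's master
# file: HCPCS J-codes are the standard permanent codes for each product;
# NDCs are representative labeled package codes (11-digit, zero-padded).
# Override with --code-map / load_drug_code_maps(path) for production lists.
#
# dosing_interval_days is the labeled maintenance schedule used for the
# permissible-gap rule (gap = interval + grace); route is the claim stream
# on which the synthetic generator emits the drug (self-injected products
# appear as pharmacy fills, infused products as facility administrations).
adalimumab:
  ndc: ["00074379902", "00074433902"]
  hcpcs: ["J0135"]
  dosing_interval_days: 14
  route: pharmacy
certolizumab:
  ndc: ["50474070062", "50474071079"]
  hcpcs: ["J0717"]
  dosing_interval_days: 28
  route: pharmacy
golimumab:
  ndc: ["57894007002", "57894007102"]
  hcpcs: ["J1602"]
  dosing_interval_days: 28
  route: pharmacy
infliximab:
  ndc: ["57894003001"]
  hcpcs: ["J1745"]
  dosing_interval_days: 56
  route: medical
natalizumab:
  ndc: ["59075073015"]
  hcpcs: ["J2323"]
  dosing_interval_days: 28
  route: medical
ustekinumab:
  ndc: ["57894006002", "57894006103"]
  hcpcs: ["J3357"]
  dosing_interval_days: 56
  route: pharmacy
vedolizumab:
  ndc: ["64764030020"]
  hcpcs: ["C9026", "J3380"]
  dosing_interval_days: 56
  route: medical
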