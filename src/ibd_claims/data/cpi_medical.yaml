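# Annual averages of the US Medical Care Component of the Consumer Price
# Index (BLS series CUUR0000SAM, 1982-84=100). Costs in service year y are
# restated to US$2015 by multiplying by index[2015]/index[y].
2009: 375.613
2010: 388.436
2011: 400.258
2012: 414.924
2013: 425.134
2014: 435.292
2015: 446.752
2016: 463.675
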