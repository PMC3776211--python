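A2M
B2M
GSN
LRP1
DDIT4
MAL
APOEREG001
APOEREG002
APOEREG003
APOEREG004
APOEREG005
APOEREG006
APOEREG007
APOEREG008
APOEREG009
APOEREG010
APOEREG011
APOEREG012
APOEREG013
APOEREG014
APOEREG015
APOEREG016
APOEREG017
APOEREG018
APOEREG019
APOEREG020
APOEREG021
APOEREG022
APOEREG023
APOEREG024
APOEREG025
APOEREG026
APOEREG027
APOEREG028
APOEREG029
APOEREG030
APOEREG031
APOEREG032
APOEREG033
APOEREG034
APOEREG035
APOEREG036
APOEREG037
APOEREG038
APOEREG039
APOEREG040
APOEREG041
APOEREG042
APOEREG043
APOEREG044
APOEREG045
APOEREG046
APOEREG047
APOEREG048
APOEREG049
APOEREG050
APOEREG051
APOEREG052
APOEREG053
APOEREG054
APOEREG055
APOEREG056
APOEREG057
APOEREG058
APOEREG059
APOEREG060
APOEREG061
APOEREG062
APOEREG063
APOEREG064
APOEREG065
APOEREG066
APOEREG067
APOEREG068
APOEREG069
APOEREG070
APOEREG071
APOEREG072
APOEREG073
APOEREG074
APOEREG075
APOEREG076
APOEREG077
APOEREG078
APOEREG079
APOEREG080
APOEREG081
APOEREG082
APOEREG083
APOEREG084
APOEREG085
APOEREG086
APOEREG087
APOEREG088
APOEREG089
APOEREG090
APOEREG091
APOEREG092
APOEREG093
APOEREG094
APOEREG095
APOEREG096
APOEREG097
APOEREG098
APOEREG099
APOEREG100
APOEREG101
APOEREG102
APOEREG103
APOEREG104
APOEREG105
APOEREG106
APOEREG107
APOEREG108
APOEREG109
APOEREG110
APOEREG111
APOEREG112
APOEREG113
APOEREG114
APOEREG115
APOEREG116
APOEREG117
APOEREG118
APOEREG119
APOEREG120
APOEREG121
APOEREG122
APOEREG123
APOEREG124
APOEREG125
APOEREG126
APOEREG127
APOEREG128
APOEREG129
APOEREG130
APOEREG131
APOEREG132
APOEREG133
APOEREG134
APOEREG135
APOEREG136
APOEREG137
APOEREG138
APOEREG139
APOEREG140
APOEREG141
APOEREG142
APOEREG143
APOEREG144
APOEREG145
APOEREG146
APOEREG147
APOEREG148
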