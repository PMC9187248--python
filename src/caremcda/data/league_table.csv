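project_id,capacity,outcomes,integration,workforce,risk,total,net_cost,cost_per_point
4,0,0.0,0.7,1,2.0,3.7,210950,57014
5,0,0.4,1.3,0,1.0,2.7,238476,88324
15,2,1.2,2.0,2,1.5,8.7,784865,90214
14,0,0.0,1.3,2,1.5,4.8,471029,98131
11,1,1.2,2.0,1,2.0,7.2,913336,126852
17,2,1.2,1.3,1,0.5,6.0,821383,136897
3,1,1.2,2.0,0,1.5,5.7,850006,149124
12,2,0.4,1.3,0,2.0,5.7,889698,156087
10,0,0.0,1.0,0,0.0,1.0,162954,162954
7,0,0.8,1.3,2,1.5,5.6,1362603,243322
9,1,0.4,1.3,0,0.5,3.2,792507,247658
2,2,1.2,0.7,2,1.5,7.4,1842953,249048
13,0,0.8,0.7,1,0.5,3.0,786052,262017
6,2,0.4,2.0,1,2.0,7.4,2048999,276892
16,2,1.6,1.3,2,1.5,8.4,2411938,287135
8,0,0.4,1.0,1,0.5,2.9,1277109,440382
1,0,0.0,0.7,0,0.5,1.2,1675243,1396036
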