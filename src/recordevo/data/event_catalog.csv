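index,event_id,name,category,direction,unit
1,100m,100m sprint,sprint,minimize,seconds
2,200m,200m sprint,sprint,minimize,seconds
3,400m,400m running,middle/long running,minimize,seconds
4,800m,800m running,middle/long running,minimize,seconds
5,3000m,3000m running,middle/long running,minimize,seconds
6,10000m,"10,000m running",middle/long running,minimize,seconds
7,marathon,marathon,marathon,minimize,seconds
8,100m_back,100m backstroke,swim,minimize,seconds
9,200m_back,200m backstroke,swim,minimize,seconds
10,100m_breast,100m breaststroke,swim,minimize,seconds
11,200m_breast,200m breaststroke,swim,minimize,seconds
12,100m_fly,100m butterfly,swim,minimize,seconds
13,200m_fly,200m butterfly,swim,minimize,seconds
14,50m_free,50m freestyle,swim,minimize,seconds
15,100m_free,100m freestyle,swim,minimize,seconds
16,200m_free,200m freestyle,swim,minimize,seconds
17,400m_free,400m freestyle,swim,minimize,seconds
18,800m_free,800m freestyle,swim,minimize,seconds
19,200m_im,200m medley,swim,minimize,seconds
20,400m_im,400m medley,swim,minimize,seconds
21,400m_h,400m hurdles,hurdles,minimize,seconds
22,long_jump,long jump,jump,maximize,meters
23,high_jump,high jump,jump,maximize,meters
24,triple_jump,triple jump,jump,maximize,meters
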